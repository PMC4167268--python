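"""Independent reference implementations used as oracles in the tests.

Everything here is deliberately written from first principles — explicit
source/detector-frame assembly, scalar triple loops, time-domain convolution,
quadrature — and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


# -- geometry oracle --------------------------------------------------------


def project_point_reference(dso, dsd, point, angle):
    """(u, v, w2) for a world point via explicit ray/plane intersection.

    Assembles the source position and detector frame by hand:
    source at angle theta sits at -dso * c_hat with c_hat the unit vector
    from source toward the origin; the detector plane passes through
    source + dsd * c_hat with in-plane basis (t_hat, z_hat).
    """
    c_hat = np.array([np.cos(angle), np.sin(angle), 0.0])
    t_hat = np.array([-np.sin(angle), np.cos(angle), 0.0])
    z_hat = np.array([0.0, 0.0, 1.0])
    source = -dso * c_hat
    rel = np.asarray(point, float) - source
    depth = rel @ c_hat  # distance from source along the central ray
    if depth <= 0:
        return np.nan, np.nan, np.nan
    hit = source + (dsd / depth) * rel  # intersection with detector plane
    center = source + dsd * c_hat
    u = (hit - center) @ t_hat
    v = (hit - center) @ z_hat
    w2 = dso**2 / depth**2
    return u, v, w2


# -- filtering oracles ------------------------------------------------------


def rl_kernel_closed_form(n, spacing):
    """Ramachandran-Lakshminarayanan band-limited ramp kernel sample h(n)."""
    if n == 0:
        return 1.0 / (4.0 * spacing**2)
    if n % 2 == 0:
        return 0.0
    return -1.0 / (np.pi**2 * n**2 * spacing**2)


def filter_row_time_domain(row, H, out_len):
    """Circular time-domain convolution of a zero-padded row with ifft(H)."""
    pad = len(H)
    h = np.fft.ifft(H).real
    padded = np.zeros(pad)
    padded[: len(row)] = row
    out = np.zeros(out_len)
    for n in range(out_len):
        acc = 0.0
        for m in range(len(row)):
            acc += padded[m] * h[(n - m) % pad]
        out[n] = acc
    return out


def cosine_weight_reference(dsd, u, v):
    return dsd / np.hypot(dsd, np.hypot(u, v))


# -- backprojection oracle --------------------------------------------------


def bilinear_reference(img, col, row):
    """Scalar bilinear sample of img at fractional (column, row), 0 outside."""
    rows, cols = img.shape
    c0, r0 = int(np.floor(col)), int(np.floor(row))
    fc, fr = col - c0, row - r0
    val = 0.0
    for dr, wr in ((0, 1 - fr), (1, fr)):
        for dc, wc in ((0, 1 - fc), (1, fc)):
            cc, rr = c0 + dc, r0 + dr
            if 0 <= cc < cols and 0 <= rr < rows:
                val += wr * wc * img[rr, cc]
    return val


def backproject_view_reference(values, grid, geom, q, angle, scale):
    """Literal triple-loop accumulation of one filtered view into values."""
    ox, oy, oz = grid.origin
    for i in range(grid.nx):
        for j in range(grid.ny):
            for k in range(grid.nz):
                p = (ox + i * grid.dx, oy + j * grid.dy, oz + k * grid.dz)
                u, v, w2 = project_point_reference(geom.dso, geom.dsd, p, angle)
                if not np.isfinite(u):
                    continue
                col = (u - geom.det_offset_u) / geom.det_spacing_u + (geom.det_cols - 1) / 2
                row = (v - geom.det_offset_v) / geom.det_spacing_v + (geom.det_rows - 1) / 2
                values[i, j, k] += scale * w2 * bilinear_reference(q, col, row)


def fdk_reference(stack, grid, H):
    """Reference pipeline: cosine weight, time-domain filter, triple loop."""
    geom = stack.geom
    u = (np.arange(geom.det_cols) - (geom.det_cols - 1) / 2) * geom.det_spacing_u \
        + geom.det_offset_u
    v = (np.arange(geom.det_rows) - (geom.det_rows - 1) / 2) * geom.det_spacing_v \
        + geom.det_offset_v
    W = cosine_weight_reference(geom.dsd, u[None, :], v[:, None])
    values = np.zeros(grid.shape)
    scale = 0.5 * (geom.angle_spacing) * geom.dsd / geom.dso
    for n, angle in enumerate(geom.angles):
        weighted = stack.data[n].astype(float) * W
        q = np.zeros_like(weighted)
        for r in range(geom.det_rows):
            q[r] = filter_row_time_domain(weighted[r], H, geom.det_cols)
        backproject_view_reference(values, grid, geom, q, angle, scale)
    return values


# -- phantom oracle ---------------------------------------------------------


def chord_by_quadrature(ellipsoid, origin, direction, rel_step=1e-4):
    """Trapezoid integration of the inside-indicator along the ray."""
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    center = np.asarray(ellipsoid.center)
    R = max(ellipsoid.semi_axes)
    # parameter window guaranteed to contain the intersection
    t_mid = (center - origin) @ direction
    span = 2.5 * R
    step = rel_step * R
    ts = np.arange(t_mid - span, t_mid + span, step)
    pts = origin[None, :] + ts[:, None] * direction[None, :]
    inside = ellipsoid.contains(pts).astype(float)
    return np.trapezoid(inside, dx=step)
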