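"""The ramp filter and its apodization windows.

Prints the first spatial-domain samples of the discrete ramp kernel next to
the Ramachandran-Lakshminarayanan closed form, then shows how apodization
windows trade resolution for noise suppression by damping the response at
high frequencies.
"""

import numpy as np

import conefdk as cf

du = 1.0
pad = 65536
H = cf.ramp_kernel(cf.FilterSpec(window="ramp", pad_length=pad), du)
h = np.fft.ifft(H).real / du

print("n   discrete h(n)   closed form")
for n in range(5):
    exact = 0.25 if n == 0 else (0.0 if n % 2 == 0 else -1.0 / (np.pi**2 * n**2))
    print(f"{n}   {h[n]: .6e}   {exact: .6e}")

print("\nresponse at half-Nyquist and Nyquist (relative to pure ramp):")
f = np.fft.fftfreq(256, d=du)
ramp = cf.ramp_kernel(cf.FilterSpec("ramp", pad_length=256), du)
for window in ("shepp-logan", "hamming", "hann"):
    Hw = cf.ramp_kernel(cf.FilterSpec(window, pad_length=256), du)
    half = np.argmin(np.abs(f - 0.25))
    nyq = 128
    print(f"{window:12s}  f=0.25/du: {Hw[half] / ramp[half]:.3f}"
          f"   f=Nyquist: {Hw[nyq] / max(ramp[nyq], 1e-300):.3f}")
# The unwindowed ramp keeps full amplitude up to the band limit (sharpest
# images, most noise); Hann rolls off to exactly zero at Nyquist.
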