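"""Split an RR series into LF/HF1/HF2/HF3 by wavelet packets.

The RR series is modulated at 0.30 Hz, so nearly all band energy should
land in HF2 (0.25-0.35 Hz).
"""

import numpy as np

from hrvemotion import compute_rri, decompose_bands, resample_rri
from hrvemotion.bands import BAND_NAMES, band_energy
from hrvemotion.synthetic import SynthSpec, synth_ecg

spec = SynthSpec(duration=300.0, snr_db=None, rr_jitter_s=0.0, seed=4,
                 modulations={"HF2": (0.05, 0.30)})
_, truth = synth_ecg(spec)

rri = compute_rri(truth, spec.fs)
uniform = resample_rri(rri, fs_u=4.0)
signals = decompose_bands(uniform)

energies = band_energy(signals)
total = sum(energies.values())
for band in BAND_NAMES:
    lo, hi = signals[band].lo, signals[band].hi
    print(f"{band:4s} {lo:.2f}-{hi:.2f} Hz  energy fraction "
          f"{energies[band] / total:.3f}")
recon = sum(signals[k].samples for k in list(BAND_NAMES) + ["_residual"])
print(f"reconstruction residual: "
      f"{np.linalg.norm(recon - uniform.samples):.2e}")
print("The 0.30 Hz RR modulation concentrates in HF2; the five parts sum")
print("back to the input exactly (perfect reconstruction).")
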