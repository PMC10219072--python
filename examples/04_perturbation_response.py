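"""Perturbation response scanning on the elastic network.

Applies unit forces at every site through the 20 slowest nonzero modes
and ranks sites as signal effectors (row means) and sensors (column
means).
"""

import numpy as np

from allostery import synth
from allostery.enm import build_anm, prs_scan

ref = synth.make_reference(synth.SyntheticSpec())
anm = build_anm(ref)  # 12 A cutoff springs
pm = prs_scan(anm, n_modes=20)

eff, sens = pm.effectiveness, pm.sensitivity
top_eff = np.argsort(-eff)[:3]
top_sens = np.argsort(-sens)[:3]
fmt = lambda idx: ", ".join(
    f"{ref.labels[i]} ({ref.sites[i].domain.value if ref.sites[i].domain else 'LINKER'})"
    for i in idx
)
print("top effector sites (influence when perturbed):", fmt(top_eff))
print("top sensor sites (sensitivity to perturbations):", fmt(top_sens))
print("-> rows of the PRS map say how strongly a site broadcasts a")
print("   perturbation; columns say how strongly it feels one.")
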