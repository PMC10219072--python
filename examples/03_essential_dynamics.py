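"""Essential dynamics: PCA variance fractions, cosine content, FEL basins.

Diagonalises the fluctuation covariance of a sampled ensemble, reports
how much motion the leading components carry, and maps the free-energy
landscape over (PC1, PC2).
"""

from allostery import essential, synth
from allostery.enm import build_anm

ref = synth.make_reference(synth.SyntheticSpec())
anm = build_anm(ref)
ens = synth.sample_anm_ensemble(anm, 2000, kT=1.0, seed=1)

cov = essential.covariance(ens, align=False)
modes = essential.pca(cov, n_components=20)
print(f"PC1 variance fraction: {modes[0]['variance_fraction']:.1%}")
print(f"first 20 components:   {modes[-1]['cumulative_fraction']:.1%} of total motion")

p1 = essential.project(ens, cov, 0)
p2 = essential.project(ens, cov, 1)
print(f"cosine content of PC1: {essential.cosine_content(p1):.2e} "
      "(<= 0.1 means the motion is not random-diffusion-like)")

# ~2000 frames: 20 bins per axis keeps bin counts high enough that the
# Gaussian basin is not shattered into sampling-noise minima
fel = essential.free_energy_landscape(p1.values, p2.values, n_bins=20)
basins = essential.detect_basins(fel, depth_threshold=1.0)
print(f"free-energy basins within 1 kT of the minimum: {len(basins)}")
print("deepest basin at (PC1, PC2) = (%.1f, %.1f)" % (basins[0]["x"], basins[0]["y"]))
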