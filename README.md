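# ki67gan

Ki67-conditioned histology-patch generation and evaluation, at desk scale.

The Ki67 index quantifies cell proliferation: in an immunohistochemistry
(IHC) patch it is the fraction of pixels belonging to DAB-brown (Ki67
positive) nuclei.  Routine HE staining cannot show Ki67 directly, so HE
patches are annotated from Ki67 patches cut from adjacent tissue sections.
`ki67gan` implements the full experimental loop around a conditional
style-based generative model of HE patches:

* **synthdata** — synthetic HE/Ki67 patch pairs with exact ground-truth
  indices, an imbalanced label distribution (mode below 0.1, ~2 % above
  0.5), and controllable quality defects; everything downstream is testable
  without any external data.
* **annotate** — the semi-automated annotation pipeline: k-means colour
  clustering of Ki67 patches, index quantification as the brown-pixel
  fraction, and a quality filter (blur / edge / blob / tissue / blank
  statistics) that excludes low-information HE patches.
* **cgan** — a compact conditional style-based GAN.  The Ki67 index enters
  through the mapping network: `w = FC₂(FC₁(concat(norm(z), norm(FC(c)))))`
  with second-moment normalisation, exactly the conditional mapping-network
  contract; the synthesis stack is style-modulated and CPU-trainable, the
  discriminator uses projection conditioning, and training applies the
  non-saturating loss with an R1 penalty (γ = 2) counted in kimgs.
* **metrics** — FID, FHD (FID with a trained Ki67-regressor embedding) and
  PPL against a pluggable embedder contract, with
  `d²(a,b) = ‖μ_a−μ_b‖² + tr(Σ_a+Σ_b−2(Σ_aΣ_b)^{1/2})`.
* **intervals** — the Ki67-interval protocol: the six-interval hierarchy,
  assignment, FID/FHD cross matrices with expectation flags, and a
  violation detector that reproduces the published anomaly calls.
* **sequences** — Ki67-sweep sequences (one latent, c = 0 → 0.5 in steps
  of 0.1) and a Spearman trend statistic through the annotation oracle.
* **ratings** — ordinal analysis of the two pathologists' published
  5-level verdicts (shipped as transcribed CSV fixtures): inter-rater
  distances, consistency fractions and category summaries.

## Worked example

```python
import numpy as np
from ki67gan import annotate, cgan, synthdata

# 2,000 annotated synthetic pairs, imbalanced labels, 64x64
pairs = synthdata.make_dataset(2000, size=64, seed=11)
images = np.stack([p.he_image for p in pairs])
labels = np.array([p.true_index for p in pairs])

# train the conditional generator for 50 kimgs (about ten minutes on CPU)
config = cgan.TrainingConfig(total_kimgs=50.0, gamma=2.0, seed=1)
checkpoint, log = cgan.train((images, labels), config)

# sweep the condition and recover the index from the generated HE images
rng = np.random.default_rng(7)
for c in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
    imgs, _ = cgan.generate_conditional(checkpoint, c, 50, rng)
    est = np.mean([annotate.estimate_he_index(im) for im in imgs])
    print(f"c={c:.1f}  recovered index {est:.3f}")
```

Output from the run above:

```
c=0.0  recovered index 0.000
c=0.1  recovered index 0.149
c=0.2  recovered index 0.228
c=0.3  recovered index 0.246
c=0.4  recovered index 0.264
c=0.5  recovered index 0.247
```

The recovered index rises with the conditioning value (Spearman ρ ≈ 0.74
over 300 images) and saturates above c ≈ 0.3, where the imbalanced label
distribution provides very few real examples — the same weakness the
interval evaluation protocol flags for the ⟨0.2,0.5) range.  Sweeping c
with a fixed latent (`sequences.generate_sequence_group`) yields a median
per-sequence trend of 0.94 versus −0.14 for a label-shuffled control.

The same pipeline is available from the shell:

```bash
ki67gan synth make --n 2000 --size 64 --seed 11 --out data/
ki67gan annotate --manifest data/manifest.csv
ki67gan gan train --manifest data/manifest.labeled.csv --kimgs 50 --gamma 2 --seed 1 --out run/
ki67gan sequences --ckpt run/ckpt-final.npz --n 20 --seed 8 --out run/sequences
ki67gan ratings --group 1
```

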