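"""ChIP-qPCR fold enrichment, replicate testing and the cell-mixture model.

Simulates a noisy qPCR plate in which a target promoter is 20-fold enriched
over an ACTB-like control amplicon, computes fold enrichment per replicate,
tests two conditions against each other, and predicts the enrichment of a
10%/90% mixed cell population under linear chromatin pooling.
"""

from bivalency.qpcr import (
    MixtureSpec,
    fold_enrichment,
    mixture_expected_enrichment,
    replicate_test,
)
from bivalency.simulate import simulate_qpcr_plate

signals = {
    ("erythroid", "HBA", "chip"): 60.0, ("erythroid", "HBA", "input"): 3.0,
    ("erythroid", "ACTB", "chip"): 3.0, ("erythroid", "ACTB", "input"): 3.0,
    ("lymphoid", "HBA", "chip"): 3.0, ("lymphoid", "HBA", "input"): 3.0,
    ("lymphoid", "ACTB", "chip"): 3.0, ("lymphoid", "ACTB", "input"): 3.0,
}
plate = simulate_qpcr_plate(signals, noise_sd=0.15, n_replicates=3, seed=42)

folds = {(f.sample, f.amplicon): f for f in fold_enrichment(plate, "ACTB")}
for (sample, amplicon), f in sorted(folds.items()):
    print(f"{sample:<10} {amplicon:<5} fold = {f.mean_fold:6.2f} +/- {f.sd:.2f} "
          f"(n = {f.n_replicates})")
# The HBA fold in erythroid cells should sit near the programmed 20x; in
# lymphoid cells near 1 (no enrichment over the control amplicon).

ery = folds[("erythroid", "HBA")].replicate_folds
ly = folds[("lymphoid", "HBA")].replicate_folds
t, p = replicate_test(ery, ly)  # Student's t on log2 folds
print(f"\nerythroid vs lymphoid HBA enrichment: t = {t:.2f}, p = {p:.4f}")

mixture = MixtureSpec((("erythroid", 0.1, 20.0), ("lymphoid", 0.9, 1.0)))
print(f"expected fold for a 10%/90% mixture: {mixture_expected_enrichment(mixture):.2f}")
# Linear pooling: a 10% highly-enriched subpopulation leaves a clear (2.9x)
# signal in the bulk measurement — detectable, unlike a true per-cell
# co-occupancy, which requires sequential ChIP.
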