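"""Run the pleiotropy-robust sensitivity battery with outlier correction.

Simulates a dataset containing two horizontally pleiotropic outliers,
removes them with MR-PRESSO, and compares the outlier-corrected IVW
(the primary endpoint) with MR-Egger, weighted median, weighted mode and
MR-RAPS on the corrected SNP set.
"""

import numpy as np

from mrsuite import (
    PressoConfig,
    SimConfig,
    egger,
    ivw,
    mr_raps,
    run_presso,
    simulate_summary_stats,
    weighted_median,
    weighted_mode,
)
from mrsuite.simulate import harmonize_simulated

exposure, outcome, truth = simulate_summary_stats(
    SimConfig(n_snp=30, true_b=-0.10, seed=8)
)
data = harmonize_simulated(exposure, outcome)
for k in (3, 17):  # inject two pleiotropic outliers
    data.pairs[k].beta_out += 9 * data.pairs[k].se_out

presso = run_presso(data, PressoConfig(n_sim=4999, seed=1))
print(f"MR-PRESSO: RSS_obs = {presso.rss_obs:.2f}, global p = {presso.global_p:.4g}")
print(f"outliers flagged: {presso.outlier_snp_ids} (distortion p = {presso.distortion_p})")
print(f"raw IVW        b = {presso.estimate_raw.b:+.3f}")
print(f"corrected IVW  b = {presso.estimate_corrected.b:+.3f}  <- primary endpoint\n")

keep = np.setdiff1d(np.arange(len(data.pairs)), np.array(presso.outlier_indices))
corrected = data.subset(keep)

rows = [("IVW (corrected)", presso.estimate_corrected)]
eg = egger(corrected)
rows.append(("MR-Egger", eg.slope))
rows.append(("weighted median", weighted_median(corrected, seed=2)))
rows.append(("weighted mode", weighted_mode(corrected, seed=3)))
rows.append(("MR-RAPS", mr_raps(corrected)))

print(f"{'method':18s} {'b':>8s} {'95% CI':>20s} {'p':>10s}")
for name, e in rows:
    print(f"{name:18s} {e.b:+8.3f} [{e.ci_low:+.3f}, {e.ci_high:+.3f}]  {e.pval:10.3g}")
print(f"\nEgger intercept = {eg.intercept:+.4f} (p = {eg.intercept_p:.3f}); "
      f"I2_GX = {eg.i2_gx:.3f}")
print(f"\nThe generating truth was b = {truth.true_b}; concordant estimates across")
print("methods with a null Egger intercept indicate the effect is not driven by")
print("directional pleiotropy. I2_GX near 1 supports the NOME assumption.")
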