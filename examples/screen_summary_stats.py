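"""Screen a harmonized GWAS/GWIS panel for interaction and mediation.

Builds a small synthetic pair of summary-statistic files (a GWAS with
marginal effects and a GWIS with main/environment/interaction effects),
harmonizes them, estimates the bridging coefficient theta with the
iterative pleiotropy-removal (IMRP) scheme, and screens every variant
with the MR-based interaction+mediation statistic.
"""

import tempfile
from pathlib import Path

from click.testing import CliRunner

from mrgxe import (harmonize, imrp_estimate, estimate_overlap_corr,
                   read_sumstats, screen_panel, select_instruments,
                   standardize_effects, two_step)
from mrgxe.cli import main as cli

workdir = Path(tempfile.mkdtemp())
CliRunner().invoke(cli, ["make-fixtures", "--n1", "8000", "--n2", "8000",
                         "--n0", "8000", "--beta3", "0.5", "--seed", "5",
                         "--out", str(workdir)])

gwas = read_sumstats(workdir / "gwas.tsv")
gwis = read_sumstats(workdir / "gwis.tsv")
panel = standardize_effects(harmonize(gwas, gwis))
print(f"harmonized panel: {len(panel)} variants "
      f"(filter log: {panel.filter_log})")

instruments = select_instruments(panel)  # p < 5e-8 after GC, 500 kb / r2 0.1
r = estimate_overlap_corr(panel)         # from null variants' z-scores
effect = imrp_estimate(instruments, overlap_corr=r)
print(f"theta = {effect.theta_hat:.3f} +- {effect.se_theta:.3f} "
      f"({effect.n_iv} instruments, r = {r:.2f}, "
      f"{len(effect.removed_ids)} removed as pleiotropic)")

results = screen_panel(panel, effect)
confirmed = two_step(results, screen_alpha=1e-4, n_exposures=1)
hits = confirmed[confirmed["two_step_pass"]]
print(f"{int(confirmed['screen_pass'].sum())} variants pass the MR screen; "
      f"{len(hits)} confirmed by the direct interaction test")
print(hits[["variant_id", "p_mr", "p_direct"]].to_string(index=False))

# theta is the slope relating GWIS main effects to GWAS marginal effects
# across ordinary variants (departures from 1 absorb heterogeneity in
# trait processing and effect standardization between the two sources);
# screen hits depart from that regression line, i.e. they carry
# gene-environment interaction and/or mediation through E.
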