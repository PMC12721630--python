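"""Cox survival models and mediation of the Lp(a) effect by vascular
superoxide.

The exposure (alternative vs reference GRS group) is fit with and without
log basal superoxide.  Under the full-mediation generator the unadjusted
hazard ratio is elevated and the adjusted one collapses toward 1 — the
nested-model signature of mediation.
"""

import numpy as np

import redoxmr as rx
from redoxmr.causal import mediation_cox
from redoxmr.pipeline import SURVIVAL_COVARIATES

# a larger cohort makes the mediation pattern unambiguous
cfg = rx.SimulationConfig(n_subjects=20000, seed=42)
gm, pheno = rx.simulate_cohort(cfg)
grs = rx.build_grs(gm, gm.rsids)

keep = np.isin(grs.group, ["reference", "alternative"])
res = mediation_cox(
    pheno.loc[keep, "followup_years"].to_numpy(),
    pheno.loc[keep, "cv_death"].to_numpy(),
    (grs.group == "alternative").astype(float)[keep],
    np.log(pheno.loc[keep, "basal_o2"].to_numpy()),
    covariates=pheno.loc[keep, SURVIVAL_COVARIATES])

u, a = res.unadjusted, res.mediator_adjusted
print(f"n={res.n}, events={res.n_events}")
print(f"unadjusted        HR {u[0]:.3f} [95% CI {u[1][0]:.3f}-{u[1][1]:.3f}], p={u[2]:.2e}")
print(f"superoxide-adjusted HR {a[0]:.3f} [95% CI {a[1][0]:.3f}-{a[1][1]:.3f}], p={a[2]:.3f}")
print(f"attenuation of the exposure log-HR: {res.attenuation_pct:.1f}%")
rho = res.exposure_mediator_rho
print(f"exposure-mediator Spearman rho={rho.statistic:.3f} (p={rho.p:.1e}): "
      f"correlated but far from collinear")
# Loss of significance after adjusting for the mediator, with near-total
# attenuation, is the qualitative pattern of full mediation.
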