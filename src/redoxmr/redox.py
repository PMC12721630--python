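"""Derived quantities for the vascular superoxide bioassays and plasma
biopterins, plus the Lp(a) tertile grouping used throughout the analysis.

The chemiluminescence panel has four raw readouts per subject (RLU): basal
superoxide, superoxide after NOS inhibition with L-NAME, NADPH-stimulated
superoxide and NADPH-stimulated superoxide after the pan-NOX inhibitor
Vas2870.  Two derived indices isolate the enzymatic sources:

* ``lname_delta = post_lname_o2 - basal_o2`` — the L-NAME-induced change;
  positive values index uncoupled-eNOS-derived superoxide, negative values
  carry recoupled/NO-scavenging physiology and are retained, never clipped;
* ``vas2870_inhibitable = nadph_o2 - post_vas2870_o2`` — the NOX
  contribution.

The biopterin panel reduces to the BH4/BH2 ratio, an index of eNOS-cofactor
bioavailability.  Natural-log transforms of the positive readouts are
exposed for the linear models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import DataError

__all__ = [
    "RedoxPanel",
    "BiopterinPanel",
    "derive_redox_indices",
    "tertile_groups",
]

_RAW_COLUMNS = ["basal_o2", "post_lname_o2", "nadph_o2", "post_vas2870_o2"]
_BIOPTERIN_COLUMNS = ["bh4", "bh2"]


@dataclass(frozen=True)
class RedoxPanel:
    basal_o2: float
    post_lname_o2: float
    nadph_o2: float
    post_vas2870_o2: float

    @property
    def lname_delta(self) -> float:
        return self.post_lname_o2 - self.basal_o2

    @property
    def vas2870_inhibitable(self) -> float:
        return self.nadph_o2 - self.post_vas2870_o2


@dataclass(frozen=True)
class BiopterinPanel:
    bh4: float
    bh2: float

    @property
    def ratio(self) -> float:
        return self.bh4 / self.bh2


def derive_redox_indices(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append the derived redox/biopterin columns (``_derived`` suffix) to a
    phenotype table.  Idempotent: existing derived columns are recomputed.

    Raises on any nonpositive raw readout, naming the offending subjects.
    """
    for col in _RAW_COLUMNS + _BIOPTERIN_COLUMNS:
        if col not in cohort.columns:
            raise DataError(f"phenotype table lacks required column {col!r}")
        vals = cohort[col]
        bad = cohort.loc[vals.isna() | (vals <= 0), "subject_id"]
        if len(bad):
            raise DataError(
                f"nonpositive or missing {col} for subjects: "
                + ", ".join(map(str, bad.head(5)))
                + ("..." if len(bad) > 5 else "")
            )
    out = cohort.copy()
    out["lname_delta_derived"] = out["post_lname_o2"] - out["basal_o2"]
    out["vas2870_inhibitable_derived"] = out["nadph_o2"] - out["post_vas2870_o2"]
    out["bh_ratio_derived"] = out["bh4"] / out["bh2"]
    for col in _RAW_COLUMNS:
        out[f"log_{col}_derived"] = np.log(out[col])
    return out


def tertile_groups(values, contrast: str = "low_vs_medhigh") -> np.ndarray:
    """Split values at the empirical 1/3 and 2/3 quantiles (linear
    interpolation) and label the two-group contrast.

    ``low_vs_medhigh`` (default): bottom tertile = "low", upper two = "medhigh".
    ``high_vs_lowmed``: top tertile = "high", lower two = "lowmed".
    Subjects exactly on a cut point go to the lower group.
    """
    x = np.asarray(values, dtype=float).ravel()
    if np.any(~np.isfinite(x)):
        raise DataError("tertile grouping requires finite values")
    if np.unique(x).size < 3:
        raise DataError("tertile grouping needs at least 3 distinct values")
    q1, q2 = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
    tert = np.where(x <= q1, 0, np.where(x <= q2, 1, 2))
    for t, cut in ((0, q1), (1, q2), (2, q2)):
        if np.sum(tert == t) == 0:
            tie_mass = float(np.mean(x == cut))
            raise DataError(
                f"ties leave tertile {t + 1} empty (tie mass {tie_mass:.2f} "
                f"at cut point {cut:g})"
            )
    if contrast == "low_vs_medhigh":
        return np.where(tert == 0, "low", "medhigh")
    if contrast == "high_vs_lowmed":
        return np.where(tert == 2, "high", "lowmed")
    raise ValueError(f"unknown contrast {contrast!r}")
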