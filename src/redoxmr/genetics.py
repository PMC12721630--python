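"""Genotype I/O, per-variant association with log-Lp(a), genetic risk score
construction, and two-locus linkage disequilibrium via an EM haplotype
estimator.

The genetic instrument follows the unweighted dominant-model design used for
LPA-region scores in surgical cohorts: a subject's score is the number of the
seven instrument SNPs at which they carry at least one alternative allele.
Subjects carrying none are the *reference* group, subjects carrying >=3 the
*alternative* group, and 1-2 carriers stay unassigned for the dichotomous
contrast.  A continuous per-SD form of the score is defined within the
stratum of subjects carrying alternative alleles at more than one variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import DataError
from .inference import bh_fdr

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "AssocResult",
    "GrsResult",
    "LdPair",
    "read_genotypes",
    "write_genotypes",
    "snp_association",
    "build_grs",
    "em_haplotype_freqs",
    "ld_stats",
    "ld_matrices",
]

#: missing-dosage sentinel in the integer dosage matrix
MISSING: int = -1


# ---------------------------------------------------------------------------
# genotype container and I/O
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix with values {0,1,2} and a missing code."""

    subject_ids: list[str]
    rsids: list[str]
    dosage: np.ndarray  # int16, MISSING for no-call
    chrom: list[str] | None = None
    pos: list[int] | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        if self.dosage.shape != (len(self.subject_ids), len(self.rsids)):
            raise DataError("dosage shape does not match subject/variant counts")
        valid = np.isin(self.dosage, [MISSING, 0, 1, 2])
        if not valid.all():
            raise DataError("dosages must be 0, 1, 2 or the missing code")
        if len(set(self.rsids)) != len(self.rsids):
            raise DataError("duplicate rsids in genotype matrix")
        if self.chrom is None:
            self.chrom = ["6"] * len(self.rsids)
        if self.pos is None:
            self.pos = list(range(160_000_000, 160_000_000 + 1000 * len(self.rsids), 1000))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def missing_fraction(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def column(self, rsid: str) -> np.ndarray:
        return self.dosage[:, self.rsids.index(rsid)]

    def alt_freq(self) -> np.ndarray:
        """Empirical alternative-allele frequency per variant (complete case)."""
        out = np.empty(len(self.rsids))
        for j in range(len(self.rsids)):
            col = self.dosage[:, j]
            obs = col[col != MISSING]
            out[j] = np.nan if obs.size == 0 else obs.sum() / (2.0 * obs.size)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, columns=self.rsids)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    rsids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        rsid = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise DataError(f"multiallelic record rejected: {rsid}")
        gts = var.genotypes  # [allele1, allele2, phased]
        dos = np.empty(len(subjects), dtype=np.int16)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                dos[i] = MISSING
            else:
                dos[i] = a + b
        rsids.append(rsid)
        chrom.append(str(var.CHROM))
        pos.append(int(var.POS))
        cols.append(dos)
    if not cols:
        raise DataError(f"no variant records in {path}")
    return GenotypeMatrix(subjects, rsids, np.column_stack(cols), chrom, pos)


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise DataError(f"{path}: dosage TSV must have a subject_id column")
    rsids = [c for c in df.columns if c != "subject_id"]
    dosage = df[rsids].to_numpy(dtype=float)
    dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int16)
    return GenotypeMatrix(df["subject_id"].tolist(), rsids, dosage)


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF (GT field, diploid, biallelic) or a
    dosage TSV.  ``fmt`` defaults from the file suffix."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _vcf_contig_lines(chrom: list[str]) -> str:
    seen: list[str] = []
    for c in chrom:
        if c not in seen:
            seen.append(c)
    return "".join(f"##contig=<ID={c}>\n" for c in seen)


def write_genotypes(gm: GenotypeMatrix, path, fmt: str | None = None) -> None:
    """Write a genotype matrix as a VCF v4.2 subset (GT only) or a dosage TSV."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "tsv":
        gm.to_frame().to_csv(path, sep="\t", index=False)
        return
    if fmt != "vcf":
        raise ValueError(f"unknown genotype format {fmt!r}")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_vcf_contig_lines(gm.chrom))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.subject_ids)
            + "\n"
        )
        for j, rsid in enumerate(gm.rsids):
            gts = "\t".join(gt_map[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t{rsid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# per-variant association
# ---------------------------------------------------------------------------


@dataclass
class AssocResult:
    rsid: str
    beta: float
    se: float
    p: float
    q: float
    n: int
    excluded: bool = False
    reason: str | None = None

    def to_dict(self) -> dict:
        return {"rsid": self.rsid, "beta": self.beta, "se": self.se,
                "p": self.p, "q": self.q, "n": self.n,
                "excluded": self.excluded, "reason": self.reason}


def snp_association(
    gm: GenotypeMatrix,
    lpa,
    gw_threshold: float = 5.0e-8,
) -> tuple[list[AssocResult], list[str]]:
    """Additive quantitative-trait test per variant: simple linear regression
    of log-Lp(a) on dosage, complete case, with BH-FDR q-values over the
    tested variants.  Monomorphic variants are flagged and excluded, not an
    abort.  Returns the per-variant results and the rsids with p below the
    genome-wide threshold."""
    lpa = np.asarray(lpa, dtype=float).ravel()
    if len(lpa) != gm.n_subjects:
        raise DataError("lpa vector must align with genotype subjects")
    if np.any(lpa <= 0):
        raise DataError("Lp(a) must be positive (mg/dL) for the log transform")
    y_all = np.log(lpa)

    results: list[AssocResult] = []
    tested_idx: list[int] = []
    for j, rsid in enumerate(gm.rsids):
        d = gm.dosage[:, j]
        keep = d != MISSING
        x = d[keep].astype(float)
        y = y_all[keep]
        n = int(keep.sum())
        if n < 3:
            results.append(AssocResult(rsid, math.nan, math.nan, math.nan,
                                       math.nan, n, True, "fewer than 3 calls"))
            continue
        if np.all(x == x[0]):
            results.append(AssocResult(rsid, math.nan, math.nan, math.nan,
                                       math.nan, n, True, "monomorphic"))
            continue
        xc = x - x.mean()
        yc = y - y.mean()
        sxx = float(xc @ xc)
        beta = float(xc @ yc) / sxx
        resid = yc - beta * xc
        df = n - 2
        sigma2 = float(resid @ resid) / df
        se = math.sqrt(sigma2 / sxx)
        if se == 0:
            p = 1e-300
        else:
            p = max(float(2.0 * sps.t.sf(abs(beta) / se, df)), 1e-300)
        results.append(AssocResult(rsid, beta, se, p, math.nan, n))
        tested_idx.append(len(results) - 1)

    if tested_idx:
        qs = bh_fdr([results[i].p for i in tested_idx])
        for i, q in zip(tested_idx, qs):
            results[i].q = float(q)
    selected = [results[i].rsid for i in tested_idx if results[i].p < gw_threshold]
    return results, selected


# ---------------------------------------------------------------------------
# genetic risk score
# ---------------------------------------------------------------------------


@dataclass
class GrsResult:
    subject_ids: list[str]
    carrier_count: np.ndarray  # per-subject 0..k over nonmissing instruments
    group: np.ndarray  # "reference" | "alternative" | "unassigned"
    continuous_score: np.ndarray  # per-SD among carrier_count >= 2, NaN elsewhere
    complete: np.ndarray  # all instrument dosages observed
    instrument_rsids: list[str] = field(default_factory=list)

    @property
    def group_sizes(self) -> dict[str, int]:
        return {g: int(np.sum(self.group == g))
                for g in ("reference", "alternative", "unassigned")}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "carrier_count": self.carrier_count,
                "group": self.group,
                "continuous_score": self.continuous_score,
                "complete": self.complete,
            }
        )


def build_grs(gm: GenotypeMatrix, instrument_rsids: list[str]) -> GrsResult:
    """Unweighted summative (dominant-model) genetic risk score.

    carrier_count counts instrument variants with dosage >= 1 among the
    subject's nonmissing calls; reference requires an observed 0 at every
    instrument variant, alternative requires carrier_count >= 3, and 1-2
    carriers are unassigned.  The continuous per-SD score standardizes
    carrier_count within the carrier_count >= 2 stratum.
    """
    missing_rs = [r for r in instrument_rsids if r not in gm.rsids]
    if missing_rs:
        raise DataError("instrument variants absent from matrix: " + ", ".join(missing_rs))
    cols = [gm.rsids.index(r) for r in instrument_rsids]
    d = gm.dosage[:, cols]
    observed = d != MISSING
    carrier = (d >= 1) & observed
    cc = carrier.sum(axis=1).astype(int)
    complete = observed.all(axis=1)

    group = np.full(gm.n_subjects, "unassigned", dtype=object)
    group[cc >= 3] = "alternative"
    group[(cc == 0) & complete] = "reference"

    cont = np.full(gm.n_subjects, np.nan)
    stratum = cc >= 2
    if stratum.sum() >= 2:
        vals = cc[stratum].astype(float)
        sd = vals.std(ddof=1)
        if sd > 0:
            cont[stratum] = (vals - vals.mean()) / sd
        else:
            cont[stratum] = 0.0
    return GrsResult(
        subject_ids=list(gm.subject_ids),
        carrier_count=cc,
        group=np.asarray(group),
        continuous_score=cont,
        complete=complete,
        instrument_rsids=list(instrument_rsids),
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


@dataclass
class LdPair:
    rsid_a: str
    rsid_b: str
    hap_freqs: tuple[float, float, float, float]  # pAB, pAb, paB, pab
    D: float = math.nan
    D_prime: float = math.nan
    r2: float = math.nan
    em_iterations: int = 0
    converged: bool = False
    non_identifiable: bool = False
    log_likelihood: float = math.nan
    loglik_trace: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"rsid_a": self.rsid_a, "rsid_b": self.rsid_b,
                "hap_freqs": list(self.hap_freqs), "D": self.D,
                "D_prime": self.D_prime, "r2": self.r2,
                "em_iterations": self.em_iterations, "converged": self.converged,
                "non_identifiable": self.non_identifiable}


def _two_locus_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    keep = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[keep], g2[keep]
    counts = np.zeros((3, 3), dtype=float)
    for a in range(3):
        for b in range(3):
            counts[a, b] = np.sum((g1 == a) & (g2 == b))
    return counts


def two_locus_loglik(hap: np.ndarray, counts: np.ndarray) -> float:
    """Observed-data multinomial log-likelihood of unphased two-locus genotypes
    under haplotype frequencies (pAB, pAb, paB, pab).

    Genotype coding: dosage of the *alternative* allele; haplotype "A"/"B"
    denote carrying the alternative allele at locus one / two.
    """
    pAB, pAb, paB, pab = hap
    # P(g1, g2): sum over unordered haplotype pairs consistent with the pair
    probs = np.empty((3, 3))
    probs[2, 2] = pAB**2
    probs[2, 1] = 2 * pAB * pAb
    probs[2, 0] = pAb**2
    probs[1, 2] = 2 * pAB * paB
    probs[1, 1] = 2 * pAB * pab + 2 * pAb * paB
    probs[1, 0] = 2 * pAb * pab
    probs[0, 2] = paB**2
    probs[0, 1] = 2 * paB * pab
    probs[0, 0] = pab**2
    with np.errstate(divide="ignore"):
        lp = np.where(counts > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
    return float(np.sum(counts * lp))


def em_haplotype_freqs(
    g1,
    g2,
    rsid_a: str = "a",
    rsid_b: str = "b",
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LdPair:
    """Two-locus haplotype frequency estimation from unphased genotypes by EM.

    Only double heterozygotes carry latent phase; every other genotype pair
    determines its two gametes.  Convergence when the largest absolute change
    in any haplotype frequency falls below ``tol``.
    """
    g1 = np.asarray(g1, dtype=np.int16).ravel()
    g2 = np.asarray(g2, dtype=np.int16).ravel()
    counts = _two_locus_counts(g1, g2)
    n = counts.sum()
    if n < 2:
        raise DataError("EM needs at least 2 subjects with complete calls")
    for label, margin in (("first", counts.sum(axis=1)), ("second", counts.sum(axis=0))):
        alleles = margin @ np.array([0.0, 1.0, 2.0])
        if alleles == 0 or alleles == 2 * n:
            raise DataError(f"{label} locus is monomorphic; haplotypes undefined")

    # fixed gamete contributions from unambiguous genotypes (counts of AB, Ab, aB, ab)
    fixed = np.zeros(4)
    # hap order: AB, Ab, aB, ab ; "A" = alt at locus 1, "B" = alt at locus 2
    contrib = {
        (2, 2): (2, 0, 0, 0), (2, 1): (1, 1, 0, 0), (2, 0): (0, 2, 0, 0),
        (1, 2): (1, 0, 1, 0), (1, 0): (0, 1, 0, 1),
        (0, 2): (0, 0, 2, 0), (0, 1): (0, 0, 1, 1), (0, 0): (0, 0, 0, 2),
    }
    for (a, b), c in contrib.items():
        fixed += counts[a, b] * np.asarray(c, dtype=float)
    n_dh = counts[1, 1]  # double heterozygotes: AB/ab or Ab/aB

    non_ident = bool(n_dh == n and n_dh > 0)

    # initialize at linkage equilibrium from allele frequencies
    pA = (counts.sum(axis=1) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
    pB = (counts.sum(axis=0) @ np.array([0.0, 1.0, 2.0])) / (2 * n)
    hap = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    hap = np.maximum(hap, 1e-12)
    hap /= hap.sum()

    it = 0
    converged = False
    trace: list[float] = [two_locus_loglik(hap, counts)]
    for it in range(1, max_iter + 1):
        pAB, pAb, paB, pab = hap
        denom = pAB * pab + pAb * paB
        w = 0.5 if denom == 0 else (pAB * pab) / denom
        e = fixed.copy()
        e += n_dh * np.array([w, 1 - w, 1 - w, w])
        new = e / (2 * n)
        delta = float(np.max(np.abs(new - hap)))
        hap = new
        trace.append(two_locus_loglik(hap, counts))
        if delta < tol:
            converged = True
            break

    return LdPair(
        rsid_a=rsid_a,
        rsid_b=rsid_b,
        hap_freqs=tuple(float(h) for h in hap),
        em_iterations=it,
        converged=converged,
        non_identifiable=non_ident,
        log_likelihood=trace[-1],
        loglik_trace=trace,
    )


def ld_stats(pair_or_freqs) -> LdPair:
    """Compute D, D' and r-squared from two-locus haplotype frequencies.

    D = pAB − pA·pB; D' = |D| / Dmax with Dmax = min(pA·pb, pa·pB) for D>0
    and min(pA·pB, pa·pb) for D<0; r² = D² / (pA·pa·pB·pb).
    """
    if isinstance(pair_or_freqs, LdPair):
        pair = pair_or_freqs
        hap = np.asarray(pair.hap_freqs, dtype=float)
    else:
        hap = np.asarray(pair_or_freqs, dtype=float)
        pair = LdPair("a", "b", tuple(float(h) for h in hap))
    if hap.shape != (4,) or np.any(hap < -1e-12) or abs(hap.sum() - 1) > 1e-6:
        raise DataError("haplotype frequencies must be 4 nonnegative values summing to 1")
    pAB, pAb, paB, pab = hap
    pA, pB = pAB + pAb, pAB + paB
    pa, pb = 1 - pA, 1 - pB
    if min(pA, pa, pB, pb) <= 0:
        raise DataError("monomorphic locus: D'/r2 undefined")
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * pb, pa * pB)
    elif D < 0:
        dmax = min(pA * pB, pa * pb)
    else:
        dmax = math.nan
    pair.D = float(D)
    pair.D_prime = 0.0 if D == 0 else float(abs(D) / dmax)
    pair.r2 = float(D * D / (pA * pa * pB * pb))
    return pair


def ld_matrices(gm: GenotypeMatrix, rsids: list[str] | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame, list[LdPair]]:
    """All-pairs LD: returns (D' matrix, r² matrix, pair list)."""
    rsids = rsids or gm.rsids
    k = len(rsids)
    dp = np.full((k, k), np.nan)
    r2 = np.full((k, k), np.nan)
    pairs: list[LdPair] = []
    for i in range(k):
        dp[i, i] = 1.0
        r2[i, i] = 1.0
        for j in range(i + 1, k):
            pair = em_haplotype_freqs(gm.column(rsids[i]), gm.column(rsids[j]),
                                      rsids[i], rsids[j])
            pair = ld_stats(pair)
            dp[i, j] = dp[j, i] = pair.D_prime
            r2[i, j] = r2[j, i] = pair.r2
            pairs.append(pair)
    return (pd.DataFrame(dp, index=rsids, columns=rsids),
            pd.DataFrame(r2, index=rsids, columns=rsids), pairs)
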