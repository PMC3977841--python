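"""Case-control association statistics for region-level copy-number loss.

Implements the exact statistics applied to the printed contingency tables:
two-sided Fisher's exact test by hypergeometric enumeration under the
minimum-likelihood rule, odds ratios with Woolf (log-OR normal) 95%
confidence intervals and Haldane–Anscombe continuity correction for
zero-cell tables, Pearson chi-square comparisons of cohort characteristics,
the JDS→NGSP HbA1c conversion, and the combined multi-region loss
cross-tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .status import RegionStatusMatrix


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Case/control × exposed/unexposed counts.

    a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @classmethod
    def from_status(
        cls, matrix: RegionStatusMatrix, region: str
    ) -> "ContingencyTable2x2":
        """Loss vs non-loss by group; missing statuses never count as loss."""
        col = matrix.statuses[region]
        case = matrix.groups == "case"
        loss = col == "loss"
        return cls(
            a=int((case & loss).sum()),
            b=int((case & ~loss).sum()),
            c=int((~case & loss).sum()),
            d=int((~case & ~loss).sum()),
        )


@dataclass
class AssociationResult:
    """Fisher P, odds ratio and 95% CI for one 2×2 table."""

    table: ContingencyTable2x2
    p_fisher: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    method_flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["table"] = [self.table.a, self.table.b, self.table.c, self.table.d]
        return d


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Exact two-sided P by full hypergeometric enumeration.

    Over all tables with the observed margins, probabilities no greater than
    the observed table's (within a 1e-9 relative tolerance, guarding
    floating-point ties) are summed — the minimum-likelihood two-sided
    convention. Degenerate tables with a zero margin have a single
    admissible table and return 1.
    """
    n = t.n
    if n == 0:
        raise ValueError("Fisher test undefined for the all-zero table")
    row1, col1 = t.a + t.b, t.a + t.c
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = stats.hypergeom.pmf(t.a, n, row1, col1)
    include = pmf <= p_obs * (1 + 1e-9)
    if include.all():  # observed table is modal: the sum is exactly 1
        return 1.0
    return min(float(pmf[include].sum()), 1.0)


def odds_ratio_ci(
    t: ContingencyTable2x2, alpha: float = 0.05
) -> tuple[float, float, float, dict]:
    """Odds ratio with Woolf log-normal CI; returns (OR, lo, hi, flags).

    OR = (a·d)/(b·c); CI = exp(ln OR ± z·sqrt(1/a+1/b+1/c+1/d)). If any cell
    is zero the Haldane–Anscombe +0.5 correction is applied to all cells and
    flagged — never silently.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    flags = {"haldane_correction": False, "sided": "two-sided-min-likelihood"}
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flags["haldane_correction"] = True
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    return float(or_), float(lo), float(hi), flags


def associate(t: ContingencyTable2x2, alpha: float = 0.05) -> AssociationResult:
    or_, lo, hi, flags = odds_ratio_ci(t, alpha=alpha)
    return AssociationResult(
        table=t,
        p_fisher=fisher_exact_two_sided(t),
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        method_flags=flags,
    )


def chi_square_test(table, correction: bool = True) -> float:
    """Pearson chi-square P; Yates continuity correction by default for 2×2.

    Accepts a :class:`ContingencyTable2x2` or any r×c count array. A zero
    row/column margin makes expected counts zero and raises.
    """
    counts = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    apply_correction = correction and counts.shape == (2, 2)
    res = stats.chi2_contingency(counts, correction=apply_correction)
    return float(res.pvalue)


def ngsp_from_jds(hba1c_jds: float) -> float:
    """HbA1c on the NGSP scale from the older JDS scale: NGSP% = JDS% + 0.4."""
    if hba1c_jds < 0:
        raise ValueError("HbA1c cannot be negative")
    return hba1c_jds + 0.4


@dataclass(frozen=True)
class ClinicalRecord:
    """One subject's clinical covariates (HbA1c stored on the NGSP scale)."""

    subject_id: str
    sex_male: bool
    onset_age: float | None
    family_history: bool
    exam_age: float | None
    max_bmi: float | None
    hba1c_ngsp: float | None
    postprandial_glucose: float | None
    insulin_therapy: bool
    urinary_c_peptide: float | None


CLINICAL_CONTINUOUS = [
    "onset_age", "exam_age", "max_bmi", "hba1c_ngsp",
    "postprandial_glucose", "urinary_c_peptide",
]
CLINICAL_BINARY = ["male", "family_history", "insulin_therapy"]


def combined_loss_status(
    matrix: RegionStatusMatrix, region_subset: list[str] | None = None
) -> pd.DataFrame:
    """Per-subject count of loss regions and the all-loss flag.

    Missing statuses never count as loss. Returns a DataFrame indexed by
    subject with columns group, loss_count, all_loss.
    """
    regions = region_subset if region_subset is not None else matrix.regions
    if not regions:
        raise ValueError("region_subset must be nonempty")
    unknown = [r for r in regions if r not in matrix.statuses.columns]
    if unknown:
        raise ValueError(f"unknown region labels: {unknown}")
    loss = (matrix.statuses[regions] == "loss").sum(axis=1)
    return pd.DataFrame(
        {
            "group": matrix.groups,
            "loss_count": loss.astype(int),
            "all_loss": loss == len(regions),
        }
    )


def association_report(
    matrix: RegionStatusMatrix,
    clinical: pd.DataFrame | None = None,
    regions: list[str] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Full association report: per-region tables, combined-loss counts, clinic.

    Per region: the 2×2 loss table with Fisher P, OR and CI (flagged
    non-estimable when no subject in either group carries the loss). The
    combined section cross-tabulates subjects by number of loss regions
    (0..k) per group and tests the all-regions and exactly-two contrasts.
    When a clinical table is supplied, case subjects with losses in all
    regions are compared against the remaining cases: Welch t-tests for
    continuous traits, Fisher's exact test for binary ones.
    """
    groups = set(matrix.groups)
    if groups != {"case", "control"}:
        raise ValueError("association requires both case and control subjects")
    regions = regions if regions is not None else matrix.regions
    n_cases = int((matrix.groups == "case").sum())
    n_controls = int((matrix.groups == "control").sum())
    report: dict = {"n_cases": n_cases, "n_controls": n_controls, "regions": {}}
    for region in regions:
        t = ContingencyTable2x2.from_status(matrix, region)
        res = associate(t, alpha=alpha)
        entry = res.to_dict()
        entry["estimable"] = (t.a + t.c) > 0 and (t.b + t.d) > 0
        report["regions"][region] = entry

    combined = combined_loss_status(matrix, regions)
    counts = {
        group: {
            k: int(((combined["group"] == group) & (combined["loss_count"] == k)).sum())
            for k in range(len(regions) + 1)
        }
        for group in ("case", "control")
    }
    k_all = len(regions)
    all_table = ContingencyTable2x2(
        a=counts["case"][k_all], b=n_cases - counts["case"][k_all],
        c=counts["control"][k_all], d=n_controls - counts["control"][k_all],
    )
    report["combined"] = {
        "loss_count_by_group": counts,
        "all_regions": associate(all_table, alpha=alpha).to_dict(),
    }
    if k_all >= 2:
        two_table = ContingencyTable2x2(
            a=counts["case"].get(k_all - 1, 0),
            b=n_cases - counts["case"].get(k_all - 1, 0),
            c=counts["control"].get(k_all - 1, 0),
            d=n_controls - counts["control"].get(k_all - 1, 0),
        )
        report["combined"]["exactly_two"] = {
            "table": [two_table.a, two_table.b, two_table.c, two_table.d],
            "p_fisher": fisher_exact_two_sided(two_table),
        }
    if clinical is not None:
        report["clinical"] = _clinical_comparison(matrix, combined, clinical)
    return report


def _clinical_comparison(
    matrix: RegionStatusMatrix, combined: pd.DataFrame, clinical: pd.DataFrame
) -> dict:
    cases = combined.index[combined["group"] == "case"]
    cases = cases.intersection(clinical.index)
    flag = combined.loc[cases, "all_loss"]
    carriers, others = cases[flag], cases[~flag]
    out: dict = {
        "n_all_loss_cases": int(len(carriers)),
        "n_other_cases": int(len(others)),
        "traits": {},
    }
    for trait in CLINICAL_CONTINUOUS:
        if trait not in clinical.columns:
            continue
        x = pd.to_numeric(clinical.loc[carriers, trait], errors="coerce").dropna()
        y = pd.to_numeric(clinical.loc[others, trait], errors="coerce").dropna()
        entry = {
            "kind": "continuous",
            "all_loss_mean": float(x.mean()) if len(x) else None,
            "all_loss_sd": float(x.std()) if len(x) > 1 else None,
            "other_mean": float(y.mean()) if len(y) else None,
            "other_sd": float(y.std()) if len(y) > 1 else None,
        }
        if len(x) > 1 and len(y) > 1:
            entry["p_welch"] = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
        out["traits"][trait] = entry
    for trait in CLINICAL_BINARY:
        if trait not in clinical.columns:
            continue
        x = clinical.loc[carriers, trait].astype(bool)
        y = clinical.loc[others, trait].astype(bool)
        t = ContingencyTable2x2(
            a=int(x.sum()), b=int((~x).sum()), c=int(y.sum()), d=int((~y).sum())
        )
        entry = {
            "kind": "binary",
            "all_loss_frac": f"{int(x.sum())}/{len(x)}",
            "other_frac": f"{int(y.sum())}/{len(y)}",
        }
        if t.n > 0:
            entry["p_fisher"] = fisher_exact_two_sided(t)
        out["traits"][trait] = entry
    return out
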