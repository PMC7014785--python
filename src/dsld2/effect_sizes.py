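"""Per-gene effect sizes and within-study variances from two-group data.

Two effect-size measures are supported:

MD   raw mean difference, variance sd_case^2/n_case + sd_ctrl^2/n_ctrl
SMD  standardized mean difference.  The default is Hedges-adjusted g:
     d = (mean_case - mean_ctrl) / s_pooled, multiplied by the small-sample
     correction J = 1 - 3/(4(n1+n2-2)-1), with the usual large-sample
     variance (n1+n2)/(n1 n2) + y^2 / (2(n1+n2)).  The uncorrected Cohen's d
     is available via ``correction="cohen"``.

Genes whose pooled variance is zero are rejected (MD with zero variance or
SMD with zero pooled sd would give infinite downstream weight).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MEASURES",
    "TwoGroupSummary",
    "DegenerateVarianceError",
    "md_effect",
    "smd_effect",
    "matrix_to_effects",
    "group_stats",
    "effects_from_arrays",
    "read_expression",
    "read_labels",
    "write_effects",
]

MEASURES = ("SMD", "MD")


class DegenerateVarianceError(ValueError):
    """A gene with zero sampling variance cannot enter inverse-variance pooling."""


@dataclass(frozen=True)
class TwoGroupSummary:
    """Summary statistics of one gene in one case/control study."""

    n_ctrl: int
    n_case: int
    mean_ctrl: float
    mean_case: float
    sd_ctrl: float
    sd_case: float

    def __post_init__(self):
        if self.n_ctrl < 2 or self.n_case < 2:
            raise ValueError("each group needs at least 2 samples")
        for sd in (self.sd_ctrl, self.sd_case):
            if not np.isfinite(sd) or sd < 0:
                raise ValueError("standard deviations must be finite and >= 0")


def md_effect(s: TwoGroupSummary) -> tuple[float, float]:
    """Mean difference and its sampling variance."""
    y = s.mean_case - s.mean_ctrl
    s2 = s.sd_case**2 / s.n_case + s.sd_ctrl**2 / s.n_ctrl
    if s2 <= 0:
        raise DegenerateVarianceError("zero within-study variance under MD")
    return y, s2


def smd_effect(s: TwoGroupSummary, correction: str = "hedges") -> tuple[float, float]:
    """Standardized mean difference (Hedges g by default) and its variance."""
    n1, n2 = s.n_case, s.n_ctrl
    dof = n1 + n2 - 2
    sp2 = ((n1 - 1) * s.sd_case**2 + (n2 - 1) * s.sd_ctrl**2) / dof
    if sp2 <= 0:
        raise DegenerateVarianceError("zero pooled standard deviation under SMD")
    d = (s.mean_case - s.mean_ctrl) / np.sqrt(sp2)
    if correction == "hedges":
        d *= 1.0 - 3.0 / (4.0 * dof - 1.0)
    elif correction != "cohen":
        raise ValueError("correction must be 'hedges' or 'cohen'")
    s2 = (n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2))
    return float(d), float(s2)


def group_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Row-wise mean and sd (ddof=1) of a genes x samples block."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    return values.mean(axis=1), values.std(axis=1, ddof=1), n


def effects_from_arrays(ctrl, case, measure: str = "SMD",
                        correction: str = "hedges"):
    """Vectorized per-gene effects from genes x samples control/case blocks.

    Returns ``(y, s2)`` arrays of length G.  Raises if any gene is
    degenerate (zero variance); use :func:`matrix_to_effects` for the
    flag-and-exclude behaviour.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    m0, sd0, n0 = group_stats(ctrl)
    m1, sd1, n1 = group_stats(case)
    if n0 < 2 or n1 < 2:
        raise ValueError("each group needs at least 2 samples")
    if measure == "MD":
        y = m1 - m0
        s2 = sd1**2 / n1 + sd0**2 / n0
        if np.any(s2 <= 0):
            raise DegenerateVarianceError("gene with zero within-study variance")
        return y, s2
    dof = n1 + n0 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n0 - 1) * sd0**2) / dof
    if np.any(sp2 <= 0):
        raise DegenerateVarianceError("gene with zero pooled standard deviation")
    d = (m1 - m0) / np.sqrt(sp2)
    if correction == "hedges":
        d = d * (1.0 - 3.0 / (4.0 * dof - 1.0))
    elif correction != "cohen":
        raise ValueError("correction must be 'hedges' or 'cohen'")
    s2 = (n1 + n0) / (n1 * n0) + d**2 / (2.0 * (n1 + n0))
    return d, s2


def matrix_to_effects(expr: pd.DataFrame, labels, measure: str = "SMD",
                      correction: str = "hedges", study: str = "study1") -> pd.DataFrame:
    """Per-gene effect sizes from one expression matrix (genes x samples).

    ``labels`` maps each sample column to 'case' or 'ctrl' (a Series indexed
    by sample id, a dict, or an array aligned with the columns).  Genes with
    zero pooled variance are dropped with a warning; output order otherwise
    matches input gene order.

    Returns a DataFrame with columns gene_id, study, y, s2, measure.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    if isinstance(labels, pd.Series):
        missing = [c for c in expr.columns if c not in labels.index]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")
        lab = labels.reindex(expr.columns).to_numpy()
    else:
        lab = np.asarray(labels)
        if lab.size != expr.shape[1]:
            raise ValueError("labels length does not match sample count")
    lab = np.char.lower(lab.astype(str))
    bad = set(lab) - {"case", "ctrl"}
    if bad:
        raise ValueError(f"labels must be 'case' or 'ctrl', got {sorted(bad)}")
    ctrl = expr.loc[:, lab == "ctrl"].to_numpy(dtype=float)
    case = expr.loc[:, lab == "case"].to_numpy(dtype=float)
    if ctrl.shape[1] < 2 or case.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    m0, sd0, n0 = group_stats(ctrl)
    m1, sd1, n1 = group_stats(case)
    if measure == "MD":
        keep = (sd1**2 / n1 + sd0**2 / n0) > 0
    else:
        keep = ((n1 - 1) * sd1**2 + (n0 - 1) * sd0**2) > 0
    if not keep.all():
        dropped = list(expr.index[~keep])
        warnings.warn(
            f"excluding {len(dropped)} constant gene(s) with zero variance: "
            f"{dropped[:5]}", UserWarning, stacklevel=2,
        )
    y, s2 = effects_from_arrays(ctrl[keep], case[keep], measure, correction)
    return pd.DataFrame(
        {"gene_id": expr.index[keep], "study": study, "y": y, "s2": s2,
         "measure": measure}
    )


# ---------------------------------------------------------------------------
# delimited-text IO
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples matrix: header of sample ids, first column gene id."""
    return pd.read_csv(path, sep=None, engine="python", index_col=0, comment="#")


def read_labels(path) -> pd.Series:
    """Read a two-column sample_id / group file (group in {case, ctrl})."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] != 2:
        raise ValueError("label file must have exactly two columns: sample_id, group")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def write_effects(df: pd.DataFrame, path, header_comment: str | None = None):
    """Write a long-format effects table as TSV."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
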