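"""Reproducibility and validity studies over model ensembles.

Reproducibility: pairwise TM-scores within an ensemble (all models, the
rank-1 model of each run, and run-by-run cross counts above a cutoff) probe
how sensitive a predictor is to its random seed.  Validity: every model is
structurally aligned to every usable reference chain and a panel of metrics
(TM-score, RMSD, aligned length, sequence identity, the stratified exact/Q
match counts, ESO, ESOP) is summarised.

Statistics policy: each sample is tested for normality (Shapiro-Wilk at
0.05); normal samples are reported as mean ± sd and compared with Student's
t-test, anything else as 25%/75% quantiles compared with the Wilcoxon
rank-sum test.  Significance level 0.05.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .overlap import DEFAULT_THRESHOLD, overlap_scores
from .structio import EnsembleSet, StructureModel, resolved_length
from .superpose import identity_alignment, tm_align

ALPHA = 0.05


@dataclass
class PairMatrix:
    """Symmetric matrix of pairwise TM-scores (diagonal ignored)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("pair matrix must be symmetric")

    def upper_values(self) -> np.ndarray:
        """The n(n-1)/2 unordered pair scores."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float
    q25: float
    q75: float
    min: float
    max: float
    is_normal: bool

    def report(self) -> str:
        """mean ± sd when normal, (q25, q75) otherwise — the publication
        convention for this panel."""
        if self.is_normal:
            return f"{self.mean:.2f} ± {self.sd:.2f}"
        return f"({self.q25:.2f}, {self.q75:.2f})"


@dataclass
class TestResult:
    method: str  # "t_test" | "wilcoxon"
    statistic: float
    p_value: float
    significant: bool


def _is_normal(values: np.ndarray) -> bool:
    if len(values) < 3 or np.ptp(values) < 1e-12:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.shapiro(values)
    return bool(p > ALPHA)


def summarize(values: list[float] | np.ndarray) -> SummaryStats:
    """Distribution summary following the normality-dependent convention."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    return SummaryStats(
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        q25=float(np.quantile(v, 0.25)),
        q75=float(np.quantile(v, 0.75)),
        min=float(v.min()),
        max=float(v.max()),
        is_normal=_is_normal(v),
    )


def compare(a: list[float] | np.ndarray, b: list[float] | np.ndarray) -> TestResult:
    """Two-sample comparison: t-test when both samples pass Shapiro-Wilk
    normality, Wilcoxon rank-sum otherwise; significant at α = 0.05."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if _is_normal(a) and _is_normal(b):
        stat, p = stats.ttest_ind(a, b)
        method = "t_test"
    else:
        stat, p = stats.ranksums(a, b)
        method = "wilcoxon"
    if np.isnan(p):  # both samples constant and equal
        stat, p = 0.0, 1.0
    return TestResult(method, float(stat), float(p), bool(p < ALPHA))


# ---------------------------------------------------------------------------
# Reproducibility
# ---------------------------------------------------------------------------

def pairwise_tm_matrix(ensemble: EnsembleSet) -> PairMatrix:
    """TM-score for every unordered model pair (same-sequence chains, so the
    correspondence is by construct position; normalisation by the shorter
    chain keeps the matrix symmetric)."""
    models = ensemble.models
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    n = len(models)
    M = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        aln = identity_alignment(models[i], models[j], normalize_by="shorter")
        M[i, j] = M[j, i] = aln.tm_score
    return PairMatrix([m.label for m in models], M)


def count_above(matrix: PairMatrix, cutoff: float = 0.5) -> int:
    """Number of unordered pairs with TM-score strictly above the cutoff."""
    return int(np.sum(matrix.upper_values() > cutoff))


def run_level_counts(ensemble: EnsembleSet, cutoff: float = 0.5,
                     matrix: PairMatrix | None = None) -> pd.DataFrame:
    """For each unordered run pair, how many of the m × m cross-run model
    pairs score above the cutoff (m models per run)."""
    runs = ensemble.runs()
    sizes = {r: len(ensemble.models_in_run(r)) for r in runs}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"runs have unequal sizes: {sizes}")
    if matrix is None:
        matrix = pairwise_tm_matrix(ensemble)
    df = matrix.to_frame()
    run_of = ensemble.run_of
    out = pd.DataFrame(pd.NA, index=runs, columns=runs, dtype="Int64")
    for ra, rb in itertools.combinations(runs, 2):
        la = [m.label for m in ensemble.models_in_run(ra)]
        lb = [m.label for m in ensemble.models_in_run(rb)]
        sub = df.loc[la, lb].to_numpy(dtype=float)
        out.loc[ra, rb] = out.loc[rb, ra] = int(np.sum(sub > cutoff))
    return out


def best_model_matrix(ensemble: EnsembleSet, cutoff: float = 0.5
                      ) -> tuple[PairMatrix, int]:
    """Pairwise TM-scores of the rank-1 model of each run, plus the strict
    count above the cutoff (10 runs -> 45 pairs)."""
    best = ensemble.best_models()
    sub = EnsembleSet(
        best,
        {m.label: ensemble.run_of[m.label] for m in best},
        {m.label: 1 for m in best},
    )
    mat = pairwise_tm_matrix(sub)
    return mat, count_above(mat, cutoff)


# ---------------------------------------------------------------------------
# Validity
# ---------------------------------------------------------------------------

PANEL_METRICS = (
    "tm_score", "rmsd", "aligned_length", "seq_identity",
    "exact_match_close", "exact_q_match_close", "total_q_match_close",
    "exact_match_other", "exact_q_match_other", "total_q_match_other",
    "exact_match_all", "exact_q_match_all", "total_q_match_all",
    "eso", "esop",
)


def validity_panel(ensemble: EnsembleSet | list[StructureModel],
                   references: list[StructureModel],
                   threshold: float = DEFAULT_THRESHOLD,
                   normalize_by: str = "reference") -> pd.DataFrame:
    """Align every model against every reference and tabulate the metric
    panel; one record per (model, reference) pair.

    References are expected to be pre-filtered (enough consecutive resolved
    glutamines); an empty reference list is an error, not an empty table.
    """
    models = ensemble.models if isinstance(ensemble, EnsembleSet) else list(ensemble)
    if not references:
        raise ValueError("no usable references")
    if not models:
        raise ValueError("no models")
    records = []
    for m in models:
        for ref in references:
            aln = tm_align(m, ref, normalize_by=normalize_by)
            ov = overlap_scores(aln, m, ref, threshold)
            c = ov.counts()
            records.append({
                "model": m.label,
                "reference": ref.label,
                "tm_score": aln.tm_score,
                "rmsd": aln.rmsd,
                "aligned_length": aln.aligned_length,
                "seq_identity": aln.seq_identity,
                **c,
                "exact_match_all": ov.n_exact_all,
                "exact_q_match_all": c["exact_q_match_close"] + c["exact_q_match_other"],
                "total_q_match_all": c["total_q_match_close"] + c["total_q_match_other"],
                "so": ov.so,
                "eso": ov.eso,
                "esop": ov.esop,
            })
    return pd.DataFrame.from_records(records)


def summarize_panel(panel: pd.DataFrame) -> dict[str, SummaryStats]:
    """Per-metric distribution summaries over all (model, reference) pairs."""
    return {m: summarize(panel[m].dropna().to_numpy()) for m in PANEL_METRICS}


def compare_panels(panel_a: pd.DataFrame, panel_b: pd.DataFrame
                   ) -> dict[str, TestResult]:
    """Metric-wise comparison of two ensembles' validity panels with the
    normality-dependent test policy."""
    out = {}
    for m in PANEL_METRICS:
        out[m] = compare(panel_a[m].dropna().to_numpy(),
                         panel_b[m].dropna().to_numpy())
    return out


def q_count_report(references: list[StructureModel]) -> pd.DataFrame:
    """Resolved-glutamine report over reference chains (the per-chain counts
    that drive the >= 9-consecutive-Q filter)."""
    from .structio import max_consecutive_resolved_q
    rows = [{"label": r.label,
             "resolved_q": len(r.resolved_q_positions()),
             "max_consecutive_q": max_consecutive_resolved_q(r),
             "resolved_length": resolved_length(r)}
            for r in references]
    return pd.DataFrame(rows)
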