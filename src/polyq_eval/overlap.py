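"""Exact-structure-overlap statistics for model-vs-reference comparison.

The structure overlap SO = 100·L(A)/min(Lm, Le) rewards any aligned pair;
the exact variants are stricter: a pair counts only when the two residues
occupy the *same construct position* (which, with sequence-validated input,
also means the same residue type) and — in the "close" stratum — sit within
a CA-CA distance threshold (5 Å by default) after superposition.

    ESO  = 100 · L(EA)  / min(Lm, Le)      exact matches over resolved lengths
    ESOP = 100 · L(EAQ) / min(LQm, LQe)    glutamine-only, over resolved Q counts

A one-position register shift of an otherwise perfect model sends ESO and
ESOP to zero while SO stays high — that asymmetry is the point: the exact
scores detect sequence-register errors that alignment-length scores forgive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .structio import StructureModel, resolved_length
from .superpose import AlignmentResult

DEFAULT_THRESHOLD = 5.0  # Å, CA-CA after superposition


@dataclass
class OverlapResult:
    """Stratified exact-match pairs and the derived overlap scores."""

    exact_pairs_close: list[tuple[int, int]]
    exact_pairs_other: list[tuple[int, int]]
    exact_q_close: int
    exact_q_other: int
    aligned_q_close: int
    aligned_q_other: int
    threshold: float
    so: float = field(default=float("nan"))
    eso: float = field(default=float("nan"))
    esop: float = field(default=float("nan"))

    @property
    def n_exact_close(self) -> int:
        return len(self.exact_pairs_close)

    @property
    def n_exact_other(self) -> int:
        return len(self.exact_pairs_other)

    @property
    def n_exact_all(self) -> int:
        return self.n_exact_close + self.n_exact_other

    def counts(self) -> dict[str, int]:
        """The six stratified match counts of the metric panel."""
        return {
            "exact_match_close": self.n_exact_close,
            "exact_q_match_close": self.exact_q_close,
            "total_q_match_close": self.aligned_q_close,
            "exact_match_other": self.n_exact_other,
            "exact_q_match_other": self.exact_q_other,
            "total_q_match_other": self.aligned_q_other,
        }

    def to_json(self) -> str:
        d = {"so": self.so, "eso": self.eso, "esop": self.esop,
             "threshold": self.threshold}
        d.update(self.counts())
        return json.dumps(d)


def exact_matches(alignment: AlignmentResult, model: StructureModel,
                  reference: StructureModel,
                  threshold: float = DEFAULT_THRESHOLD) -> OverlapResult:
    """Extract exact matches and Q-pair counts from a structural alignment.

    A pair (i, j) is *exact* iff i == j (same construct position); exact
    pairs are stratified by the CA-CA distance under the alignment's
    superposition into close (< threshold) and other (>= threshold).  The
    "total Qs" counts take every aligned pair whose two residues are both
    glutamine, with no position-equality requirement.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pairs = alignment.pairs
    ya = alignment.transformed_model_coords(model)
    xb = reference.ca_coords([q for _, q in pairs])
    dist = np.linalg.norm(ya - xb, axis=1)

    code_m = {r.position: r.code for r in model.residues}
    code_r = {r.position: r.code for r in reference.residues}
    qtract = set(model.construct.polyq_positions())
    close_pairs, other_pairs = [], []
    eq_close = eq_other = aq_close = aq_other = 0
    for (i, j), d in zip(pairs, dist):
        is_q = code_m[i] == "Q" and code_r[j] == "Q"
        close = d < threshold
        if i == j:
            (close_pairs if close else other_pairs).append((i, j))
            # exact Q matches are counted inside the poly-Q tract only
            if i in qtract:
                if close:
                    eq_close += 1
                else:
                    eq_other += 1
        if is_q:
            if close:
                aq_close += 1
            else:
                aq_other += 1
    return OverlapResult(close_pairs, other_pairs, eq_close, eq_other,
                         aq_close, aq_other, threshold)


def so_score(aligned_length: int, lm: int, le: int) -> float:
    """Structure overlap: 100 · L(A) / min(Lm, Le)."""
    if lm < 1 or le < 1:
        raise ValueError("chain lengths must be >= 1")
    if aligned_length > min(lm, le):
        raise ValueError("aligned length exceeds the shorter chain")
    return 100.0 * aligned_length / min(lm, le)


def eso_score(overlap: OverlapResult, lm: int, le: int,
              stratum: str = "close") -> float:
    """Exact structure overlap: 100 · L(EA) / min(Lm, Le).

    ``stratum`` selects which exact matches count: "close" (the distance
    criterion of the definition, default) or "all" (close + other).
    """
    if lm < 1 or le < 1:
        raise ValueError("chain lengths must be >= 1")
    n = {"close": overlap.n_exact_close, "all": overlap.n_exact_all}[stratum]
    return 100.0 * n / min(lm, le)


def esop_score(overlap: OverlapResult, lqm: int, lqe: int,
               stratum: str = "close") -> float:
    """Exact structure overlap of the poly-Q tract: 100 · L(EAQ) / min(LQm, LQe).

    LQm/LQe are the numbers of *resolved* glutamines in the model's and
    reference's poly-Q regions (a reference with a partially resolved tract
    is scored against what it actually resolves).
    """
    if lqm < 1 or lqe < 1:
        raise ValueError("no resolved poly-Q")
    n = {"close": overlap.exact_q_close,
         "all": overlap.exact_q_close + overlap.exact_q_other}[stratum]
    return 100.0 * n / min(lqm, lqe)


def overlap_scores(alignment: AlignmentResult, model: StructureModel,
                   reference: StructureModel,
                   threshold: float = DEFAULT_THRESHOLD) -> OverlapResult:
    """Exact-match extraction plus SO/ESO/ESOP in one call.

    ESOP counts only exact Q matches at positions inside the construct's
    poly-Q region (exact position equality already guarantees region
    agreement between model and reference).
    """
    ov = exact_matches(alignment, model, reference, threshold)
    lm, le = resolved_length(model), resolved_length(reference)
    ov.so = so_score(alignment.aligned_length, lm, le)
    ov.eso = eso_score(ov, lm, le)
    lqm = len(model.resolved_q_positions())
    lqe = len(reference.resolved_q_positions())
    if lqm >= 1 and lqe >= 1:
        ov.esop = esop_score(ov, lqm, lqe)
    return ov
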