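"""Rigid superposition, TM-score, and sequence-independent structure alignment.

All superpositions and distances use CA atoms only.  The TM-score of a
correspondence is maximised over superpositions with the standard iterative
fragment-seeded search; the aligner follows the TM-align scheme (gapless
threading and secondary-structure seeds, then alternating superposition /
dynamic programming until the residue pairing converges).

TM-score interpretation: values lie in (0, 1]; below ~0.17 two chains are no
more similar than random, above 0.5 they share a fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .structio import StructureModel

GAP_PENALTY = 0.6  # TM-align default DP gap opening penalty (no extension)
MAX_ITER = 30


@dataclass
class AlignmentResult:
    """Residue correspondence between two chains plus its quality scores.

    ``pairs`` are (model_position, reference_position) construct positions,
    strictly increasing in both coordinates.  ``rotation``/``translation``
    map model CA coordinates into the reference frame and are the transform
    that maximises the TM-score of the final pairing; ``rmsd`` is the
    least-squares RMSD over the aligned CA pairs.
    """

    pairs: list[tuple[int, int]]
    rotation: np.ndarray
    translation: np.ndarray
    tm_score: float
    rmsd: float
    aligned_length: int
    seq_identity: float

    def __post_init__(self) -> None:
        mp = [p for p, _ in self.pairs]
        rp = [q for _, q in self.pairs]
        if any(b <= a for a, b in zip(mp, mp[1:])) or any(
                b <= a for a, b in zip(rp, rp[1:])):
            raise ValueError("alignment pairs must be strictly increasing (no crossing)")
        assert self.aligned_length == len(self.pairs)

    def transformed_model_coords(self, model: StructureModel) -> np.ndarray:
        """Model CA coordinates of the aligned pairs, in the reference frame."""
        xa = model.ca_coords([p for p, _ in self.pairs])
        return xa @ self.rotation.T + self.translation

    def to_json(self) -> str:
        return json.dumps({
            "tm_score": self.tm_score,
            "rmsd": self.rmsd,
            "aligned_length": self.aligned_length,
            "seq_identity": self.seq_identity,
        })


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch(coords_a: np.ndarray, coords_b: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid transform of ``coords_a`` onto ``coords_b``.

    Returns ``(rotation, translation, rmsd)`` with ``a @ R.T + t ≈ b``; the
    rotation is proper (reflections corrected via the SVD determinant sign).
    Requires two equal-length sets of at least 3 points.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ or are not (n, 3): "
                         f"{a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    H = a0.T @ b0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = a0 @ R.T - b0
    rmsd = float(np.sqrt((diff ** 2).sum() / a.shape[0]))
    return R, t, rmsd


def _superpose_subset(xa: np.ndarray, xb: np.ndarray, idx: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    R, t, _ = kabsch(xa[idx], xb[idx])
    return R, t


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

def tm_d0(length: int) -> float:
    """Length-dependent distance scale of the TM-score denominator.

    d0 = 1.24 (L-15)^(1/3) - 1.8, with L floored at 17 and d0 floored at
    0.5 Å so short chains do not blow up the cube root.
    """
    L = max(int(length), 17)
    return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)


def _tm_from_dist2(d2: np.ndarray, d0: float, ln: int) -> float:
    return float(np.sum(1.0 / (1.0 + d2 / (d0 * d0))) / ln)


def _refine_tm(xa: np.ndarray, xb: np.ndarray, seed_idx: np.ndarray,
               d0: float, ln: int, max_iter: int = 20
               ) -> tuple[float, np.ndarray, np.ndarray]:
    """Iterative inclusion refinement from a seed subset: superpose on the
    subset, re-select pairs closer than a distance cut, repeat until the
    subset is stable.  Returns the best (score, rotation, translation)."""
    n = xa.shape[0]
    best: tuple[float, np.ndarray | None, np.ndarray | None] = (-1.0, None, None)
    idx = np.asarray(seed_idx)
    seen: set[frozenset] = set()
    for _ in range(max_iter):
        if idx.size < 3:
            break
        R, t = _superpose_subset(xa, xb, idx)
        d2 = ((xa @ R.T + t - xb) ** 2).sum(axis=1)
        score = _tm_from_dist2(d2, d0, ln)
        if score > best[0]:
            best = (score, R, t)
        cut = d0
        while True:
            sel = np.flatnonzero(d2 < cut * cut)
            if sel.size >= min(3, n):
                break
            cut += 0.5
        key = frozenset(sel.tolist())
        if key in seen:
            break
        seen.add(key)
        idx = sel
    return best


def tm_score_correspondence(xa: np.ndarray, xb: np.ndarray, ln: int,
                            seed_window: int = 7
                            ) -> tuple[float, np.ndarray, np.ndarray]:
    """TM-score of a fixed correspondence, maximised over superpositions.

    Seeds: the full pairing, its halves, and every ``seed_window``-residue
    window; each is refined by iterative distance-cut inclusion and the best
    score is kept.  Deterministic given inputs.
    """
    n = xa.shape[0]
    d0 = tm_d0(ln)
    seeds: list[np.ndarray] = [np.arange(n)]
    if n >= 6:
        seeds.append(np.arange(n // 2))
        seeds.append(np.arange(n // 2, n))
    w = min(seed_window, n)
    if w >= 3:
        for start in range(0, n - w + 1):
            seeds.append(np.arange(start, start + w))
    best = (-1.0, np.eye(3), np.zeros(3))
    for seed in seeds:
        score, R, t = _refine_tm(xa, xb, seed, d0, ln)
        if R is not None and score > best[0]:
            best = (score, R, t)
    return best


def tm_score(pairs: list[tuple[int, int]], model: StructureModel,
             reference: StructureModel, normalize_by: str = "reference") -> float:
    """TM-score of a residue correspondence between two chains.

    ``normalize_by`` selects L_N: the reference's resolved length (default,
    used for model-vs-experiment scoring), the model's, or the shorter of
    the two (symmetric; used for model-model reproducibility scoring).
    """
    if not pairs:
        raise ValueError("empty correspondence")
    from .structio import resolved_length
    lm, le = resolved_length(model), resolved_length(reference)
    ln = {"reference": le, "model": lm, "shorter": min(lm, le)}[normalize_by]
    if ln < 3:
        raise ValueError("chain too short")
    xa = model.ca_coords([p for p, _ in pairs])
    xb = reference.ca_coords([q for _, q in pairs])
    score, _, _ = tm_score_correspondence(xa, xb, ln)
    return min(score, 1.0) if score > 0 else score


def sequence_identity(pairs: list[tuple[int, int]], model: StructureModel,
                      reference: StructureModel) -> float:
    """Fraction of aligned pairs whose residue codes match."""
    if not pairs:
        raise ValueError("empty correspondence")
    cm = {r.position: r.code for r in model.residues}
    cr = {r.position: r.code for r in reference.residues}
    same = sum(1 for i, j in pairs if cm[i] == cr[j])
    return same / len(pairs)


# ---------------------------------------------------------------------------
# Dynamic programming (Needleman-Wunsch, linear gap, diagonal-preferring ties)
# ---------------------------------------------------------------------------

def _nw_align(S: np.ndarray, gap: float) -> list[tuple[int, int]]:
    """Global alignment maximising sum of S over matched cells minus gap
    penalties; returns matched index pairs (strictly increasing).  Ties are
    broken toward the diagonal, which makes the result deterministic."""
    n, m = S.shape
    NEG = -1e30
    H = np.empty((n + 1, m + 1))
    H[0, :] = -gap * np.arange(m + 1)
    H[:, 0] = -gap * np.arange(n + 1)
    H[0, 0] = 0.0
    jg = gap * np.arange(1, m + 1)
    for i in range(1, n + 1):
        diag = H[i - 1, :-1] + S[i - 1]
        up = H[i - 1, 1:] - gap
        A = np.maximum(diag, up)
        # H[i, j] = max(A[j], H[i, j-1] - gap); unrolled along the row this is
        # max_{k<=j}(A[k] + k*gap) - j*gap, seeded with the j=0 boundary value
        B = np.maximum.accumulate(np.concatenate(([H[i, 0]], A + jg)))
        H[i, 1:] = B[1:] - jg
    # traceback
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    eps = 1e-9
    while i > 0 and j > 0:
        h = H[i, j]
        if abs(h - (H[i - 1, j - 1] + S[i - 1, j - 1])) <= eps:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif abs(h - (H[i - 1, j] - gap)) <= eps:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


# ---------------------------------------------------------------------------
# TM-align-style aligner
# ---------------------------------------------------------------------------

def _ca_secondary(x: np.ndarray) -> np.ndarray:
    """Coarse 3-state secondary structure from CA geometry alone (helix=1,
    strand=2, coil=0), used only to seed the aligner."""
    n = x.shape[0]
    ss = np.zeros(n, dtype=int)
    if n < 5:
        return ss
    d = np.linalg.norm(x[:-2] - x[2:], axis=1)          # i, i+2
    d3 = np.linalg.norm(x[:-3] - x[3:], axis=1)         # i, i+3
    for i in range(1, n - 3):
        if 5.0 < d[i - 1] < 6.0 and 4.8 < d3[i - 1] < 6.2:
            ss[i] = 1
        elif d[i - 1] > 6.4 and d3[i - 1] > 9.0:
            ss[i] = 2
    return ss


def _threading_seeds(xa: np.ndarray, xb: np.ndarray, d0: float
                     ) -> list[list[tuple[int, int]]]:
    """Gapless threading: evaluate every offset, keep the two best by a
    quick superposition score."""
    n, m = xa.shape[0], xb.shape[0]
    scored = []
    for off in range(-(n - 5), m - 4):
        i0, j0 = max(0, -off), max(0, off)
        L = min(n - i0, m - j0)
        if L < 5:
            continue
        ia = np.arange(i0, i0 + L)
        ib = np.arange(j0, j0 + L)
        try:
            R, t, _ = kabsch(xa[ia], xb[ib])
        except ValueError:
            continue
        d2 = ((xa[ia] @ R.T + t - xb[ib]) ** 2).sum(axis=1)
        score = float(np.sum(1.0 / (1.0 + d2 / d0 ** 2)))
        scored.append((score, list(zip(ia.tolist(), ib.tolist()))))
    scored.sort(key=lambda s: -s[0])
    return [p for _, p in scored[:2]]


def _ss_seed(xa: np.ndarray, xb: np.ndarray) -> list[tuple[int, int]]:
    sa, sb = _ca_secondary(xa), _ca_secondary(xb)
    S = (sa[:, None] == sb[None, :]).astype(float)
    return _nw_align(S, 1.0)


def tm_align(model: StructureModel, reference: StructureModel,
             normalize_by: str = "reference") -> AlignmentResult:
    """Sequence-independent structural alignment of two chains.

    Initial pairings come from gapless threading, a secondary-structure
    string alignment, and their combination; each is refined by alternating
    {superpose on current pairs -> TM-score-based pair score matrix ->
    dynamic programming} until the pair set repeats (or 30 iterations).
    The pairing with the highest TM-score wins.  Unresolved reference
    residues never appear in pairs.
    """
    from .structio import resolved_length
    pa = model.resolved_positions()
    pb = reference.resolved_positions()
    if len(pa) < 5 or len(pb) < 5:
        raise ValueError("need at least 5 resolved residues per chain")
    xa = model.ca_coords(pa)
    xb = reference.ca_coords(pb)
    lm, le = len(pa), len(pb)
    ln = {"reference": le, "model": lm, "shorter": min(lm, le)}[normalize_by]
    d0 = tm_d0(ln)

    seeds = _threading_seeds(xa, xb, d0)
    ss = _ss_seed(xa, xb)
    if len(ss) >= 3:
        seeds.append(ss)
        # combined seed: superpose on the SS pairing, then one DP pass on a
        # distance + secondary-structure-agreement score matrix
        idx = np.array(ss)
        try:
            Rm, tv, _ = kabsch(xa[idx[:, 0]], xb[idx[:, 1]])
        except ValueError:
            Rm = None
        if Rm is not None:
            ya = xa @ Rm.T + tv
            d2 = ((ya[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
            S = 1.0 / (1.0 + d2 / d0 ** 2) + 0.5 * (
                _ca_secondary(xa)[:, None] == _ca_secondary(xb)[None, :])
            comb = _nw_align(S, GAP_PENALTY)
            if len(comb) >= 3:
                seeds.append(comb)

    best_pairs: list[tuple[int, int]] | None = None
    best_tm = -1.0
    best_Rt = (np.eye(3), np.zeros(3))
    for seed in seeds:
        pairs = seed
        seen: set[frozenset] = set()
        for _ in range(MAX_ITER):
            idx = np.array(pairs)
            if idx.shape[0] < 3:
                break
            tm, R, t = tm_score_correspondence(xa[idx[:, 0]], xb[idx[:, 1]], ln)
            if tm > best_tm:
                best_tm, best_pairs, best_Rt = tm, pairs, (R, t)
            ya = xa @ R.T + t
            d2 = ((ya[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
            S = 1.0 / (1.0 + d2 / d0 ** 2)
            new_pairs = _nw_align(S, GAP_PENALTY)
            key = frozenset(new_pairs)
            if new_pairs == pairs or key in seen:
                pairs = new_pairs
                break
            seen.add(key)
            pairs = new_pairs
        idx = np.array(pairs)
        if idx.shape[0] >= 3:
            tm, R, t = tm_score_correspondence(xa[idx[:, 0]], xb[idx[:, 1]], ln)
            if tm > best_tm:
                best_tm, best_pairs, best_Rt = tm, pairs, (R, t)

    if best_pairs is None:
        raise ValueError("alignment failed: no seed produced >= 3 pairs")
    idx = np.array(best_pairs)
    _, _, rmsd = kabsch(xa[idx[:, 0]], xb[idx[:, 1]])
    pos_pairs = [(pa[i], pb[j]) for i, j in best_pairs]
    ident = sequence_identity(pos_pairs, model, reference)
    return AlignmentResult(
        pairs=pos_pairs,
        rotation=best_Rt[0],
        translation=best_Rt[1],
        tm_score=min(best_tm, 1.0),
        rmsd=rmsd,
        aligned_length=len(pos_pairs),
        seq_identity=ident,
    )


def identity_alignment(model: StructureModel, reference: StructureModel,
                       normalize_by: str = "shorter") -> AlignmentResult:
    """Alignment by construct position (same-sequence chains): pair every
    position resolved in both, superpose by TM-score search.  This is the
    correspondence used for model-model reproducibility scoring."""
    common = sorted(set(model.resolved_positions()) & set(reference.resolved_positions()))
    if len(common) < 3:
        raise ValueError("fewer than 3 shared resolved positions")
    pairs = [(p, p) for p in common]
    from .structio import resolved_length
    lm, le = resolved_length(model), resolved_length(reference)
    ln = {"reference": le, "model": lm, "shorter": min(lm, le)}[normalize_by]
    xa = model.ca_coords(common)
    xb = reference.ca_coords(common)
    tm, R, t = tm_score_correspondence(xa, xb, ln)
    _, _, rmsd = kabsch(xa, xb)
    return AlignmentResult(pairs, R, t, min(tm, 1.0), rmsd, len(pairs),
                           sequence_identity(pairs, model, reference))
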