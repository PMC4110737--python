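"""Structure containers, PDB chain I/O, and ensemble assembly.

The unit of analysis is a single chain of a short construct (by default the
60-residue huntingtin exon-1 fragment with 17 glutamines, HTT17Q-EX1).
Experimental chains come from crystal structures in which the construct is
fused to maltose-binding protein and may have unresolved residues; predicted
and synthetic chains are complete.  Residues are indexed by *construct
position* (1-based); mapping from author/PDB numbering is an explicit integer
offset validated against the construct sequence.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: three-letter -> one-letter codes for the 20 standard amino acids
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class ChainNotFoundError(KeyError):
    """Requested chain id is absent from the coordinate file."""


class SequenceMismatchError(ValueError):
    """A mapped residue's identity conflicts with the construct sequence."""


@dataclass(frozen=True)
class ConstructDef:
    """Sequence and region partition of the analysed construct.

    Regions are inclusive 1-based intervals that tile ``1..len(sequence)``
    in order head, poly-Q, C-terminus.  Every position inside
    ``polyq_region`` must be glutamine (Q).
    """

    sequence: str
    head_region: tuple[int, int]
    polyq_region: tuple[int, int]
    cterm_region: tuple[int, int]

    def __post_init__(self) -> None:
        L = len(self.sequence)
        h, q, c = self.head_region, self.polyq_region, self.cterm_region
        if not (h[0] == 1 and h[1] + 1 == q[0] and q[1] + 1 == c[0] and c[1] == L):
            raise ValueError(
                f"regions {h}, {q}, {c} must tile 1..{L} contiguously in order"
            )
        for a, b in (h, q, c):
            if a > b:
                raise ValueError(f"empty region ({a}, {b})")
        for pos in range(q[0], q[1] + 1):
            if self.sequence[pos - 1] != "Q":
                raise ValueError(f"position {pos} in polyq_region is not Q")

    def __len__(self) -> int:
        return len(self.sequence)

    def code_at(self, position: int) -> str:
        return self.sequence[position - 1]

    def polyq_positions(self) -> range:
        a, b = self.polyq_region
        return range(a, b + 1)

    def region_of(self, position: int) -> str:
        for name, (a, b) in (
            ("head", self.head_region),
            ("polyq", self.polyq_region),
            ("cterm", self.cterm_region),
        ):
            if a <= position <= b:
                return name
        raise ValueError(f"position {position} outside construct")


# Huntingtin exon-1 17Q construct: 17-residue head, 17 glutamines, Pro-rich
# 26-residue C-terminus; regions per the crystallographic reference chains.
HTT17Q_EX1 = ConstructDef(
    sequence="MATLEKLMKAFESLKSF" + "Q" * 17 + "PPPPPPPPPPPQLPQPPPQAQPLLPQ",
    head_region=(1, 17),
    polyq_region=(18, 34),
    cterm_region=(35, 60),
)


@dataclass
class Residue:
    """One construct position with whatever backbone atoms are present.

    ``resolved`` means a CA coordinate exists (enough for alignment and
    overlap scoring); a resolved residue missing any of N/C/O is *CA-only*
    and is excluded from secondary-structure assignment.
    """

    position: int
    code: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def resolved(self) -> bool:
        return "CA" in self.atoms

    @property
    def ca_only(self) -> bool:
        return self.resolved and any(a not in self.atoms for a in ("N", "C", "O"))

    @property
    def has_full_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    def copy(self) -> "Residue":
        return Residue(self.position, self.code,
                       {k: v.copy() for k, v in self.atoms.items()})


@dataclass
class StructureModel:
    """A single chain mapped onto the construct.

    Only residues with coordinates are stored; unresolved construct
    positions are simply absent from ``residues``.
    """

    label: str
    source: str  # {"predicted", "experimental", "synthetic"}
    residues: list[Residue]
    construct: ConstructDef
    score: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("predicted", "experimental", "synthetic"):
            raise ValueError(f"unknown source {self.source!r}")
        pos = [r.position for r in self.residues]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("residue positions must be strictly increasing")
        L = len(self.construct)
        if pos and (pos[0] < 1 or pos[-1] > L):
            raise ValueError(f"residue positions outside 1..{L}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> list[int]:
        return [r.position for r in self.residues]

    def residue_at(self, position: int) -> Residue | None:
        for r in self.residues:
            if r.position == position:
                return r
        return None

    def resolved_positions(self) -> list[int]:
        return [r.position for r in self.residues if r.resolved]

    def ca_coords(self, positions: Sequence[int] | None = None) -> np.ndarray:
        """CA coordinates (n, 3) for the given construct positions (default:
        all resolved positions, in order)."""
        if positions is None:
            return np.array([r.atoms["CA"] for r in self.residues if r.resolved],
                            dtype=float).reshape(-1, 3)
        by_pos = {r.position: r for r in self.residues}
        return np.array([by_pos[p].atoms["CA"] for p in positions], dtype=float)

    def resolved_q_positions(self) -> list[int]:
        qset = set(self.construct.polyq_positions())
        return [r.position for r in self.residues if r.resolved and r.position in qset]

    def copy(self, label: str | None = None) -> "StructureModel":
        return StructureModel(label or self.label, self.source,
                              [r.copy() for r in self.residues],
                              self.construct, self.score)


@dataclass
class EnsembleSet:
    """Models grouped by prediction run and within-run rank."""

    models: list[StructureModel]
    run_of: dict[str, int]
    rank_of: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for m in self.models:
            key = (self.run_of[m.label], self.rank_of[m.label])
            if key in seen:
                raise ValueError(f"duplicate (run, rank) {key}")
            seen.add(key)
        for run in self.runs():
            ranks = sorted(self.rank_of[m.label] for m in self.models
                           if self.run_of[m.label] == run)
            if ranks != list(range(1, len(ranks) + 1)):
                raise ValueError(f"ranks in run {run} not contiguous from 1: {ranks}")

    def __len__(self) -> int:
        return len(self.models)

    def runs(self) -> list[int]:
        return sorted({self.run_of[m.label] for m in self.models})

    def models_in_run(self, run: int) -> list[StructureModel]:
        out = [m for m in self.models if self.run_of[m.label] == run]
        return sorted(out, key=lambda m: self.rank_of[m.label])

    def best_models(self) -> list[StructureModel]:
        """Rank-1 model of each run, in run order."""
        return [self.models_in_run(run)[0] for run in self.runs()]


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------

def read_pdb_chain(path: str, chain_id: str, construct: ConstructDef,
                   position_offset: int = 0, *,
                   label: str | None = None,
                   source: str = "experimental") -> StructureModel:
    """Extract one chain from a PDB file and map it onto the construct.

    Author residue number minus ``position_offset`` gives the construct
    position; residues mapping outside ``1..len(construct)`` (e.g. a fusion
    partner) are discarded.  Alternate locations are resolved to the highest
    occupancy, ties broken alphabetically by altloc id.  Only the first
    MODEL of multi-model files is used.

    Raises ``ChainNotFoundError`` if the chain id is absent and
    ``SequenceMismatchError`` if a mapped residue's identity conflicts with
    the construct sequence (insertion codes and non-standard residues in the
    mapped range are also reported loudly rather than skipped).
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if len(st) == 0:
        raise ChainNotFoundError(f"chain not found: no models in {path}")
    chain = st[0].find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(f"chain not found: {chain_id!r} in {path}")

    residues: list[Residue] = []
    L = len(construct)
    for res in chain:
        if res.het_flag == "W" or res.name == "HOH":
            continue
        num = res.seqid.num
        pos = num - position_offset
        if pos < 1 or pos > L:
            continue  # fusion partner / expression tag
        if res.seqid.icode not in (" ", "\0", ""):
            raise ValueError(
                f"insertion code {res.seqid.icode!r} at author residue {num}"
            )
        if res.name not in _THREE_TO_ONE:
            raise ValueError(f"non-standard residue {res.name} at position {pos}")
        code = _THREE_TO_ONE[res.name]
        if code != construct.code_at(pos):
            raise SequenceMismatchError(
                f"sequence mismatch at construct position {pos}: "
                f"file has {code}, construct has {construct.code_at(pos)}"
            )
        atoms: dict[str, np.ndarray] = {}
        for name in BACKBONE_ATOMS:
            best = None
            for atom in res:
                if atom.name != name:
                    continue
                key = (-atom.occ, atom.altloc or "")
                if best is None or key < best[0]:
                    best = (key, atom)
            if best is not None:
                p = best[1].pos
                atoms[name] = np.array([p.x, p.y, p.z], dtype=float)
        if atoms:
            residues.append(Residue(pos, code, atoms))
    return StructureModel(label or f"{chain_id}", source, residues, construct)


def write_pdb(model: StructureModel, path: str, chain_id: str = "A") -> None:
    """Write the model's backbone atoms as a single-chain PDB file."""
    st = gemmi.Structure()
    st.name = model.label
    md = gemmi.Model("1")
    chain = gemmi.Chain(chain_id)
    serial = 1
    for r in model.residues:
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE[r.code]
        res.seqid = gemmi.SeqId(r.position, " ")
        for name in BACKBONE_ATOMS:
            if name not in r.atoms:
                continue
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            x, y, z = (float(v) for v in r.atoms[name])
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = 0.0
            atom.serial = serial
            serial += 1
            res.add_atom(atom)
        chain.add_residue(res)
    md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


# ---------------------------------------------------------------------------
# Counting and filtering
# ---------------------------------------------------------------------------

def resolved_length(model: StructureModel) -> int:
    """Number of resolved residues (the L_m / L_e of the overlap scores)."""
    return sum(1 for r in model.residues if r.resolved)


def max_consecutive_resolved_q(model: StructureModel) -> int:
    """Longest run of consecutive resolved positions inside the poly-Q tract."""
    resolved = {r.position for r in model.residues if r.resolved}
    best = cur = 0
    for pos in model.construct.polyq_positions():
        cur = cur + 1 if pos in resolved else 0
        best = max(best, cur)
    return best


def filter_references(models: Iterable[StructureModel],
                      min_consecutive_q: int = 9) -> list[StructureModel]:
    """Keep reference chains with at least ``min_consecutive_q`` consecutive
    resolved glutamines in the poly-Q region (order preserved).

    The default of 9 — more than half of 17 — restricts validity scoring to
    chains whose poly-Q tract is meaningfully resolved.
    """
    return [m for m in models if max_consecutive_resolved_q(m) >= min_consecutive_q]


# ---------------------------------------------------------------------------
# Ensemble assembly from score tables
# ---------------------------------------------------------------------------

def read_score_table(path: str) -> pd.DataFrame:
    """Read a TSV score table (columns: label, score, optional cluster, run)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "label" not in df.columns or "score" not in df.columns:
        raise ValueError("score table needs 'label' and 'score' columns")
    return df


def select_ensemble(models: Sequence[StructureModel], scores: pd.DataFrame,
                    policy: str = "best_k_by_score", k: int = 5,
                    min_cluster_size: int = 10,
                    higher_is_better: bool | None = None) -> EnsembleSet:
    """Select the per-run model ensemble from a predictor score table.

    ``best_k_by_score``: the k best-scoring models of each run (C-score:
    higher is better; energy: lower is better — set ``higher_is_better``).
    ``best_per_cluster``: among clusters with more than ``min_cluster_size``
    members, take each cluster's lowest-energy member, then keep the k
    lowest-energy of those; two selected models never share a cluster.

    If a run has fewer than k eligible candidates, all eligible ones are
    returned and a warning is recorded on the ensemble.
    """
    if policy not in ("best_k_by_score", "best_per_cluster"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "best_per_cluster" and "cluster" not in scores.columns:
        raise ValueError("best_per_cluster needs a 'cluster' column")
    if higher_is_better is None:
        higher_is_better = policy == "best_k_by_score"

    by_label = {m.label: m for m in models}
    missing = set(scores["label"]) - set(by_label)
    if missing:
        raise ValueError(f"score table labels without models: {sorted(missing)[:5]}")
    df = scores.copy()
    if "run" not in df.columns:
        df["run"] = 1

    selected: list[StructureModel] = []
    run_of: dict[str, int] = {}
    rank_of: dict[str, int] = {}
    warn: list[str] = []
    for run, grp in df.groupby("run", sort=True):
        if policy == "best_k_by_score":
            grp = grp.sort_values("score", ascending=not higher_is_better,
                                  kind="mergesort")
            chosen = grp.head(k)
            if len(chosen) < k:
                warn.append(f"run {run}: only {len(chosen)} of {k} models available")
        else:
            sizes = grp.groupby("cluster")["label"].count()
            eligible = sizes[sizes > min_cluster_size].index
            reps = (grp[grp["cluster"].isin(eligible)]
                    .sort_values("score", kind="mergesort")
                    .groupby("cluster", sort=False).head(1))
            chosen = reps.sort_values("score", kind="mergesort").head(k)
            if len(chosen) < k:
                warn.append(
                    f"run {run}: only {len(chosen)} clusters larger than "
                    f"{min_cluster_size} members (wanted {k})"
                )
        for rank, (_, row) in enumerate(chosen.iterrows(), start=1):
            m = by_label[row["label"]]
            m = dataclasses.replace(m, score=float(row["score"]))
            selected.append(m)
            run_of[m.label] = int(run)
            rank_of[m.label] = rank
    if warn:
        warnings.warn("; ".join(warn), stacklevel=2)
    return EnsembleSet(selected, run_of, rank_of, warnings=warn)
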