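"""Kabsch-Sander secondary-structure assignment and ensemble profiling.

Eight conformational states are assigned from backbone hydrogen-bond
patterns: H (α-helix), B (isolated β-bridge), E (extended strand), G
(3₁₀-helix), I (π-helix), T (turn), S (bend), C (coil).  A ninth state M
marks construct positions with no usable backbone (unresolved or CA-only
residues of crystal chains), so experimental ensembles can be profiled
alongside complete predicted ones.

Hydrogen bonds use the Kabsch-Sander electrostatic model with the amide
hydrogen placed 1.0 Å from N opposite the preceding carbonyl; a bond exists
when the interaction energy is below -0.5 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import ConstructDef, Residue, StructureModel

SS_STATES = ("H", "B", "E", "G", "I", "T", "S", "C", "M")

HBOND_CUTOFF = -0.5    # kcal/mol
BEND_ANGLE = 70.0      # degrees
_Q = 0.084 * 332.0     # Kabsch-Sander coupling constant, kcal·Å/mol


def place_amide_hydrogen(residue: Residue, residue_prev: Residue) -> np.ndarray:
    """Backbone amide H: 1.0 Å from N, along the previous C→O direction
    reversed (i.e. anti to the preceding carbonyl oxygen)."""
    if "N" not in residue.atoms:
        raise ValueError("missing backbone atom N on donor residue")
    for name in ("C", "O"):
        if name not in residue_prev.atoms:
            raise ValueError(f"missing backbone atom {name} on preceding residue")
    d = residue_prev.atoms["C"] - residue_prev.atoms["O"]
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("degenerate C=O bond on preceding residue")
    return residue.atoms["N"] + d / n


def hbond_energy(donor: Residue, acceptor: Residue,
                 donor_h: np.ndarray) -> float:
    """Kabsch-Sander electrostatic H-bond energy (kcal/mol) between the
    N-H of ``donor`` and the C=O of ``acceptor``.

    E = 0.084 · 332 · (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN); a bond exists
    when E < -0.5 kcal/mol.  Proline has no amide hydrogen and cannot
    donate.
    """
    if donor.code == "P":
        raise ValueError("proline cannot donate a backbone hydrogen bond")
    for res, names in ((donor, ("N",)), (acceptor, ("C", "O"))):
        for name in names:
            if name not in res.atoms:
                raise ValueError(f"missing backbone atom {name}")
    N = donor.atoms["N"]
    H = donor_h
    C = acceptor.atoms["C"]
    O = acceptor.atoms["O"]
    r_on = np.linalg.norm(O - N)
    r_ch = np.linalg.norm(C - H)
    r_oh = np.linalg.norm(O - H)
    r_cn = np.linalg.norm(C - N)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # atom clash: treat as maximal bond, as Kabsch-Sander do
    return _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_matrix(model: StructureModel) -> tuple[np.ndarray, list[Residue]]:
    """bond[i, j] True when residue i's N-H donates to residue j's C=O.

    Works on the contiguous list of residues with full backbone; chain
    breaks (non-adjacent construct positions) disable the donor whose
    preceding residue is absent.
    """
    res = [r for r in model.residues if r.has_full_backbone]
    n = len(res)
    bond = np.zeros((n, n), dtype=bool)
    hpos: list[np.ndarray | None] = [None] * n
    for i in range(1, n):
        if res[i].position != res[i - 1].position + 1:
            continue  # chain break: no H placement
        if res[i].code == "P":
            continue
        hpos[i] = place_amide_hydrogen(res[i], res[i - 1])
    for i in range(n):
        if hpos[i] is None:
            continue
        for j in range(n):
            if abs(res[i].position - res[j].position) < 2:
                continue
            # cheap CA-CA distance gate (9 Å) before the energy evaluation
            if np.linalg.norm(res[i].atoms["CA"] - res[j].atoms["CA"]) > 9.0:
                continue
            e = hbond_energy(res[i], res[j], hpos[i])
            if e < HBOND_CUTOFF:
                bond[i, j] = True
    return bond, res


def assign_dssp(model: StructureModel) -> str:
    """Assign the 8-state secondary structure string over the construct.

    Positions without a full-backbone residue get M.  Pattern rules: an
    n-turn at i when the N-H of i+n bonds the C=O of i (n = 3, 4, 5); two
    consecutive 4-turns make an α-helix (H), analogously G from 3-turns and
    I from 5-turns; β-bridges from the parallel/antiparallel Kabsch-Sander
    bond patterns, extended to E when bridges ladder up; leftover turn
    positions become T; bend (S) where the CA(i-2)/CA(i)/CA(i+2) chain
    direction changes by more than 70°; everything else C.  Overlaps are
    resolved with precedence H > E > B > G > I > T > S.
    """
    L = len(model.construct)
    out = ["M"] * L
    bond, res = _hbond_matrix(model)
    n = len(res)
    if n == 0:
        return "".join(out)
    pos = [r.position for r in res]
    contiguous = np.zeros(n, dtype=bool)  # res[i] and res[i+1] adjacent
    for i in range(n - 1):
        contiguous[i] = pos[i + 1] == pos[i] + 1

    def adjacent_run(i: int, k: int) -> bool:
        """residues i..i+k are consecutive construct positions"""
        return i >= 0 and i + k < n and all(contiguous[i:i + k])

    # n-turns: H-bond from NH(i+k) to CO(i)
    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n - k):
            if adjacent_run(i, k) and bond[i + k, i]:
                turn[k][i] = True

    states = [""] * n  # candidate per residue, filled by precedence later
    mark = {s: np.zeros(n, dtype=bool) for s in ("H", "G", "I", "T", "S", "B", "E")}

    # helices: two consecutive k-turns start a helix at i covering i..i+k-1
    for k, code in ((4, "H"), (3, "G"), (5, "I")):
        for i in range(1, n - k):
            if turn[k][i - 1] and turn[k][i]:
                mark[code][i:i + k] = True

    # bridges
    partner = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            if abs(pos[i] - pos[j]) < 3:
                continue
            para = (bond[i + 1, j] and bond[j, i - 1]) or \
                   (bond[j + 1, i] and bond[i, j - 1])
            anti = (bond[i, j] and bond[j, i]) or \
                   (bond[i + 1, j - 1] and bond[j + 1, i - 1])
            if para or anti:
                partner[i, j] = True
    bridge = partner.any(axis=1)
    for i in range(n):
        if not bridge[i]:
            continue
        # a ladder: this bridge continues at an adjacent residue pair
        ladder = False
        for j in np.flatnonzero(partner[i]):
            for di, dj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < n and 0 <= jj < n and partner[ii, jj]:
                    ladder = True
        mark["E" if ladder else "B"][i] = True

    # turns: interior of any k-turn
    for k in (3, 4, 5):
        for i in np.flatnonzero(turn[k]):
            mark["T"][i + 1:i + k] = True

    # bends from CA chain-direction change
    for i in range(2, n - 2):
        if not (adjacent_run(i - 2, 2) and adjacent_run(i, 2)):
            continue
        u = res[i].atoms["CA"] - res[i - 2].atoms["CA"]
        v = res[i + 2].atoms["CA"] - res[i].atoms["CA"]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) > BEND_ANGLE:
            mark["S"][i] = True

    for i in range(n):
        for code in ("H", "E", "B", "G", "I", "T", "S"):
            if mark[code][i]:
                states[i] = code
                break
        else:
            states[i] = "C"
    for i, r in enumerate(res):
        out[r.position - 1] = states[i]
    return "".join(out)


@dataclass
class SSProfile:
    """Position × state occupancy over an ensemble of SS strings."""

    counts: pd.DataFrame      # index 1..L, columns SS_STATES, integer
    frequencies: pd.DataFrame
    n_structures: int

    def to_tsv(self, path: str) -> None:
        self.frequencies.to_csv(path, sep="\t", index_label="position")


def ss_profile(strings: list[str]) -> SSProfile:
    """Per-position state counts and relative frequencies over an ensemble.

    The missing state M participates like any other, so reference ensembles
    show where crystal resolution decays.
    """
    if not strings:
        raise ValueError("empty ensemble")
    L = len(strings[0])
    if any(len(s) != L for s in strings):
        raise ValueError("all SS strings must have equal length")
    counts = pd.DataFrame(0, index=range(1, L + 1), columns=list(SS_STATES))
    for s in strings:
        for i, ch in enumerate(s):
            if ch not in SS_STATES:
                raise ValueError(f"unknown state {ch!r}")
            counts.loc[i + 1, ch] += 1
    freq = counts.div(len(strings))
    return SSProfile(counts, freq, len(strings))


def profile_models(models: list[StructureModel]) -> SSProfile:
    """DSSP every model and profile the resulting strings."""
    return ss_profile([assign_dssp(m) for m in models])
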