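"""Shared fixtures: all structures are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from polyq_eval import HTT17Q_EX1, StructureModel, build_backbone, generate_ensemble


@pytest.fixture(scope="session")
def construct():
    return HTT17Q_EX1


@pytest.fixture(scope="session")
def ideal_model(construct):
    """Fully resolved 60-residue chain at ideal all-helix geometry."""
    dih = [(-57.0, -47.0)] * len(construct)
    return build_backbone(construct.sequence, dih, label="ideal",
                          construct=construct, source="predicted")


@pytest.fixture(scope="session")
def helix20():
    """20-residue ideal α-helix (poly-A with an interior Q run so a
    construct partition exists)."""
    seq = "A" * 8 + "QQQQ" + "A" * 8
    return build_backbone(seq, [(-57.0, -47.0)] * 20, label="helix20")


@pytest.fixture(scope="session")
def small_ensemble(construct):
    """2 runs x 3 models at moderate noise — enough for structural checks."""
    return generate_ensemble(construct, n_runs=2, models_per_run=3,
                             noise_sigma=1.0, seed=11)


def mask_positions(model: StructureModel, keep: set[int],
                   label: str | None = None) -> StructureModel:
    """Copy of a model restricted to the given construct positions."""
    out = model.copy(label or f"{model.label}_masked")
    out.residues = [r for r in out.residues if r.position in keep]
    return out


def random_coil(construct, seed: int, sigma: float = 0.0) -> StructureModel:
    """A random-dihedral chain over the construct (optionally noised)."""
    rng = np.random.default_rng(seed)
    dih = [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
           for _ in range(len(construct))]
    m = build_backbone(construct.sequence, dih, label=f"coil{seed}",
                       construct=construct, source="synthetic")
    if sigma > 0:
        for r in m.residues:
            for k in r.atoms:
                r.atoms[k] = r.atoms[k] + rng.normal(0, sigma, 3)
    return m


def rigid_copy(model: StructureModel, seed: int,
               label: str | None = None) -> StructureModel:
    """Apply a random proper rotation + translation to every atom."""
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-30, 30, 3)
    out = model.copy(label or f"{model.label}_moved")
    for r in out.residues:
        for k in r.atoms:
            r.atoms[k] = R @ r.atoms[k] + t
    return out
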