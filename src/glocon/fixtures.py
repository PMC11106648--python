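"""Synthetic ground-truth ensembles for testing the whole pipeline offline.

Chains are ideal alpha-helical Calpha traces (rise 1.5 A per residue, 100
degrees per residue, helix radius 2.3 A, giving the canonical ~3.8 A
consecutive Calpha spacing).  Conformational states are planted as rigid
hinge rotations of the chain tail — emulating inter-domain motion on the
~20 A scale — and/or local loop shifts of a few angstroms.  Per-chain
coordinate jitter models experimental noise; gap specs model unmodeled
residues.  Everything is seeded and deterministic.

The geometry is deliberately unphysical beyond the Calpha spacing: the
dissimilarity score and clustering consume nothing but Calpha positions, so
determinism matters more than side-chain realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import ChainRecord, MappingRow, MappingTable, write_superposed

HELIX_RISE = 1.5       # A per residue along the helix axis (z)
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # A

DEFAULT_ACCESSION = "SYN00001"


@dataclass(frozen=True)
class StateSpec:
    """One planted conformational state."""

    name: str
    hinge_angle_deg: float = 0.0
    hinge_residue: Optional[int] = None
    loop_shift: Optional[tuple[int, int, float]] = None  # (start, end, displacement A)


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for a multi-state, gapped, noisy synthetic ensemble."""

    n_residues: int = 60
    states: tuple[StateSpec, ...] = (
        StateSpec("open", 0.0, None),
        StateSpec("closed", 30.0, 30),
    )
    chains_per_state: int = 5
    jitter_sigma: float = 0.2          # A, per-coordinate Gaussian noise
    gap_spec: tuple[tuple[int, tuple[int, int]], ...] = ()  # (chain ordinal, (start, end))
    seed: int = 0
    accession: str = DEFAULT_ACCESSION
    author_offset: int = 0             # author numbering = reference - offset
    base_bend: Optional[tuple[int, float]] = (30, 90.0)  # (residue, angle deg)

    def __post_init__(self):
        if self.n_residues < 3:
            raise ValueError("n_residues must be >= 3")
        if self.base_bend is not None and not (1 < self.base_bend[0] < self.n_residues):
            raise ValueError("base_bend residue must be strictly inside the chain")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        for st in self.states:
            if st.hinge_residue is not None and not (1 < st.hinge_residue < self.n_residues):
                raise ValueError(
                    f"state {st.name!r}: hinge residue {st.hinge_residue} must be "
                    "strictly inside the chain"
                )
        n_chains = len(self.states) * self.chains_per_state
        for ordinal, (lo, hi) in self.gap_spec:
            if not 0 <= ordinal < n_chains:
                raise ValueError(f"gap chain ordinal {ordinal} out of range")
            if not (1 <= lo <= hi <= self.n_residues):
                raise ValueError(f"gap interval ({lo}, {hi}) outside chain")
            if self.n_residues - (hi - lo + 1) < 3:
                raise ValueError("gap leaves fewer than 3 residues")


@dataclass(frozen=True)
class Ensemble:
    """Generated ensemble: chain records, mapping table and planted labels."""

    chains: tuple[ChainRecord, ...]
    mapping: MappingTable
    labels: dict[str, str]           # chain key -> state name
    files: tuple[Path, ...] = ()


def generate_backbone(
    n: int,
    structure_id: str = "ideal",
    chain_id: str = "A",
    accession: str = DEFAULT_ACCESSION,
) -> ChainRecord:
    """Ideal alpha-helical Calpha trace of n residues, numbered 1..n."""
    if n < 3:
        raise ValueError("need at least 3 residues")
    i = np.arange(n)
    theta = np.deg2rad(HELIX_TWIST) * i
    coords = np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )
    residues = {int(k) + 1: coords[k] for k in range(n)}
    return ChainRecord(structure_id, chain_id, accession, residues)


def apply_hinge(chain: ChainRecord, hinge_residue: int, angle_deg: float) -> ChainRecord:
    """Rigidly rotate all residues after the hinge about an axis through its Calpha.

    The axis is the unit x direction, perpendicular to the synthetic helix
    axis (z), so a nonzero angle swings the post-hinge domain away like a
    closing lid.  Pre-hinge residues and the hinge itself are untouched.
    """
    nums = list(chain.residues)
    if hinge_residue not in chain.residues:
        raise ValueError(f"hinge residue {hinge_residue} not modeled in chain")
    if hinge_residue in (nums[0], nums[-1]):
        raise ValueError("hinge residue must be strictly inside the chain")
    pivot = chain.residues[hinge_residue]
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * np.array([1.0, 0.0, 0.0])).as_matrix()
    moved = {
        num: (R @ (pos - pivot) + pivot if num > hinge_residue else pos.copy())
        for num, pos in chain.residues.items()
    }
    return ChainRecord(chain.structure_id, chain.chain_id, chain.accession,
                       moved, chain.source_model)


def apply_loop_shift(
    chain: ChainRecord, start: int, end: int, displacement: float
) -> ChainRecord:
    """Translate residues in [start, end] by ``displacement`` A along +x."""
    shift = np.array([displacement, 0.0, 0.0])
    moved = {
        num: (pos + shift if start <= num <= end else pos.copy())
        for num, pos in chain.residues.items()
    }
    return ChainRecord(chain.structure_id, chain.chain_id, chain.accession,
                       moved, chain.source_model)


def perturb(chain: ChainRecord, sigma: float, seed: int | np.random.Generator) -> ChainRecord:
    """Add i.i.d. Gaussian noise (std ``sigma`` per coordinate) to every Calpha."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    moved = {
        num: pos + rng.normal(0.0, sigma, size=3) if sigma > 0 else pos.copy()
        for num, pos in chain.residues.items()
    }
    return ChainRecord(chain.structure_id, chain.chain_id, chain.accession,
                       moved, chain.source_model)


def random_rigid_motion(rng: np.random.Generator,
                        max_translation: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random proper rotation plus a random translation."""
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-max_translation, max_translation, size=3)
    return R, t


def _drop_gap(chain: ChainRecord, lo: int, hi: int) -> ChainRecord:
    kept = {n: p for n, p in chain.residues.items() if not lo <= n <= hi}
    return ChainRecord(chain.structure_id, chain.chain_id, chain.accession,
                       kept, chain.source_model)


def generate_ensemble(
    spec: EnsembleSpec,
    out_dir: str | Path | None = None,
    nmr_style_copy: bool = False,
) -> Ensemble:
    """Build the ensemble; optionally write one mmCIF per chain plus mapping TSV.

    Chain ordinals run state-major: state 0's chains first, then state 1's,
    etc.  Structure ids are ``syn001``, ``syn002``, ... with chain id A.
    When ``nmr_style_copy`` is true an extra multi-model file
    (``syn_nmr.cif``) holding jittered copies of the first chain is written,
    exercising the first-model rule.
    """
    rng = np.random.default_rng(spec.seed)
    gaps = {ordinal: iv for ordinal, iv in spec.gap_spec}

    chains: list[ChainRecord] = []
    labels: dict[str, str] = {}
    rows: list[MappingRow] = []
    ordinal = 0
    base = generate_backbone(spec.n_residues, accession=spec.accession)
    if spec.base_bend is not None:
        # a fixed structural bend shared by every state: a straight chain is
        # pathological for hinge motion (near-collinear domains change their
        # pairwise distances very little), whereas real multi-domain proteins
        # have their domains side by side
        base = apply_hinge(base, spec.base_bend[0], spec.base_bend[1])
    for state in spec.states:
        conf = base
        if state.hinge_residue is not None and state.hinge_angle_deg != 0.0:
            conf = apply_hinge(conf, state.hinge_residue, state.hinge_angle_deg)
        if state.loop_shift is not None:
            conf = apply_loop_shift(conf, *state.loop_shift)
        for _ in range(spec.chains_per_state):
            sid = f"syn{ordinal + 1:03d}"
            chain = ChainRecord(sid, "A", spec.accession, conf.residues)
            chain = perturb(chain, spec.jitter_sigma, rng)
            if ordinal in gaps:
                lo, hi = gaps[ordinal]
                chain = _drop_gap(chain, lo, hi)
                if state.hinge_residue is not None:
                    nums = chain.residue_numbers
                    if not (np.any(nums < state.hinge_residue)
                            and np.any(nums > state.hinge_residue)):
                        raise ValueError(
                            f"chain ordinal {ordinal}: gap ({lo}, {hi}) removes an "
                            f"entire hinge flank of state {state.name!r}"
                        )
            chains.append(chain)
            labels[chain.key] = state.name
            rows.append(MappingRow(sid, "A", spec.accession,
                                   1, spec.n_residues, spec.author_offset))
            ordinal += 1

    mapping = MappingTable(rows)
    files: list[Path] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for chain in chains:
            authored = _renumber(chain, -spec.author_offset)
            path = out_dir / f"{chain.structure_id}.cif"
            write_superposed([authored], None, path)
            files.append(path)
        mapping.write_tsv(out_dir / "mapping.tsv")
        files.append(out_dir / "mapping.tsv")
        with open(out_dir / "labels.json", "w") as fh:
            json.dump(labels, fh, indent=2, sort_keys=True)
        files.append(out_dir / "labels.json")
        if nmr_style_copy:
            models = [perturb(chains[0], max(spec.jitter_sigma, 0.05), rng)
                      for _ in range(3)]
            nmr_path = out_dir / "syn_nmr.cif"
            write_superposed([_renumber(m, -spec.author_offset) for m in models],
                             None, nmr_path)
            files.append(nmr_path)
    return Ensemble(tuple(chains), mapping, labels, tuple(files))


def _renumber(chain: ChainRecord, delta: int) -> ChainRecord:
    moved = {n + delta: p.copy() for n, p in chain.residues.items()}
    return ChainRecord(chain.structure_id, chain.chain_id, chain.accession,
                       moved, chain.source_model)


def two_state_spec(seed: int = 0, hinge_angle: float = 30.0, jitter: float = 0.2,
                   chains_per_state: int = 5, n_residues: int = 60) -> EnsembleSpec:
    """The canonical open/closed benchmark ensemble used throughout the tests.

    A 60-residue helix with a fixed 90-degree structural bend at residue 30,
    giving two ~45 A arms at a right angle.  The closed state swings the
    second arm a further 30 degrees toward the first, displacing the
    terminal residue by ~20 A — the scale of a real inter-domain motion —
    while 0.2 A jitter stands in for coordinate uncertainty.
    """
    return EnsembleSpec(
        n_residues=n_residues,
        states=(StateSpec("open", 0.0, None),
                StateSpec("closed", hinge_angle, n_residues // 2)),
        chains_per_state=chains_per_state,
        jitter_sigma=jitter,
        seed=seed,
    )
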