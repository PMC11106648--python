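"""Least-squares rigid superposition of Calpha traces (Kabsch algorithm).

Chains are paired residue-by-residue through their shared reference
numbering and superposed on *all* common residues.  This differs from
structurally-conserved-core superposition (GESAMT-style): for hinge or
fold-switch proteins the all-residue RMSD reported here will exceed a
core-only RMSD.  The trade-off is an exact, closed-form, fully testable
procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .clustering import ClusterAssignment
from .errors import DegenerateGeometryError, InsufficientOverlapError
from .segmentation import Segment
from .structure_io import ChainRecord

COLLINEARITY_TOL = 1e-8


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid motion ``x -> R x + t`` mapping mobile onto target, with its RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_aligned: int
    mobile: str = ""
    target: str = ""

    @property
    def transform(self) -> tuple[np.ndarray, np.ndarray]:
        return self.rotation, self.translation


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation/translation mapping points P onto points Q.

    Standard SVD solution of the orthogonal Procrustes problem with the
    reflection branch corrected to a proper rotation (det = +1).
    """
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    for pts in (P0, Q0):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= COLLINEARITY_TOL * max(s[0], 1.0):
            raise DegenerateGeometryError(
                "point set is collinear: rotation about the line is undetermined"
            )
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def kabsch_superpose(mobile: ChainRecord, target: ChainRecord) -> SuperpositionResult:
    """Superpose ``mobile`` onto ``target`` over their common residues.

    Residues are paired by reference number; at least three non-collinear
    common Calpha positions are required.
    """
    common = sorted(set(mobile.residues) & set(target.residues))
    if len(common) < 3:
        raise InsufficientOverlapError(mobile.key, target.key, len(common))
    P = mobile.coords_for(common)
    Q = target.coords_for(common)
    R, t, rmsd = _kabsch(P, Q)
    return SuperpositionResult(R, t, rmsd, len(common), mobile.key, target.key)


def superpose_segment(
    segment: Segment, reference: str
) -> dict[str, SuperpositionResult]:
    """Superpose every other chain of a segment onto the reference chain.

    Returns one result per non-reference member, keyed by chain id.  A
    common display frame needs only all-vs-reference transforms; all-vs-all
    dissimilarity is already covered by the GLOCON matrix.
    """
    ref = segment.member(reference)
    results: dict[str, SuperpositionResult] = {}
    errors = []
    for member in segment.members:
        if member.key == reference:
            continue
        try:
            results[member.key] = kabsch_superpose(member, ref)
        except (InsufficientOverlapError, DegenerateGeometryError) as exc:
            errors.append((member.key, exc))
    if errors:
        detail = "; ".join(f"{k}: {e}" for k, e in errors)
        raise RuntimeError(f"superposition onto {reference!r} failed for: {detail}")
    return results


def model_vs_representatives(
    model: ChainRecord,
    assignment: ClusterAssignment,
    chains: Mapping[str, ChainRecord] | Sequence[ChainRecord],
) -> tuple[dict[int, SuperpositionResult | None], int | None]:
    """RMSD of a predicted model against each cluster representative.

    Returns per-cluster superposition results (``None`` where the model and
    the representative share fewer than three residues — reported, never
    silently omitted) and the label of the closest state (minimum RMSD;
    ``None`` if no cluster could be compared).
    """
    if not isinstance(chains, Mapping):
        chains = {c.key: c for c in chains}
    per_cluster: dict[int, SuperpositionResult | None] = {}
    for label, rep_id in sorted(assignment.representatives.items()):
        rep = chains[rep_id]
        try:
            per_cluster[label] = kabsch_superpose(model, rep)
        except (InsufficientOverlapError, DegenerateGeometryError):
            per_cluster[label] = None
    comparable = {lbl: r.rmsd for lbl, r in per_cluster.items() if r is not None}
    closest = min(comparable, key=lambda lbl: (comparable[lbl], lbl)) if comparable else None
    return per_cluster, closest
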