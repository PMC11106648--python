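"""The GLOCON (GLObal CONformation) dissimilarity between protein chains.

The score compares two chains of identical sequence without superposing
them.  Each chain is reduced to its Calpha distance matrix — invariant to
any rigid motion — and the two matrices are compared element-wise over the
residues modeled in both chains:

1. take the absolute difference of the two distance matrices,
2. zero every element strictly below a noise threshold tau (default 3 A),
   discarding small discrepancies in Calpha placement,
3. sum the upper triangle and multiply by the fraction of segment residues
   modeled in both chains, penalizing gaps.

Two normalization modes are provided.  ``literal_product`` multiplies the
raw upper-triangle sum by the modeled fraction f.  ``mean_then_fraction``
divides by the number of summed pairs first (a per-pair mean) and then
multiplies by f, which keeps scores comparable between pairs with very
different coverage.  ``literal_product`` is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import CorruptCoordinatesError, InsufficientOverlapError, SegmentScoreError
from .segmentation import Segment
from .structure_io import ChainRecord

MAX_SANE_DISTANCE = 1e4  # A; larger pairwise distances indicate corrupt input

NORMALIZATION_MODES = ("literal_product", "mean_then_fraction")


@dataclass(frozen=True)
class GloconParams:
    """Tunable parameters of the score and the downstream dendrogram cut.

    noise_threshold : float
        tau, in angstroms.  Distance-matrix differences strictly below tau
        are zeroed.  Default 3.0.
    normalization_mode : str
        ``literal_product`` or ``mean_then_fraction`` (see module docstring).
    cut_fraction : float
        c in (0, 1]: the dendrogram is cut at c times the maximum pairwise
        score.  Default 0.7.
    """

    noise_threshold: float = 3.0
    normalization_mode: str = "literal_product"
    cut_fraction: float = 0.7

    def __post_init__(self):
        if self.noise_threshold < 0:
            raise ValueError("noise_threshold must be >= 0")
        if self.normalization_mode not in NORMALIZATION_MODES:
            raise ValueError(
                f"normalization_mode must be one of {NORMALIZATION_MODES}"
            )
        if not 0 < self.cut_fraction <= 1:
            raise ValueError("cut_fraction must be in (0, 1]")


@dataclass(frozen=True)
class CaDistanceMatrix:
    """Pairwise Calpha-Calpha Euclidean distances of one chain."""

    residue_index: tuple[int, ...]
    D: np.ndarray

    def subset(self, residue_numbers: Sequence[int]) -> np.ndarray:
        pos = {n: i for i, n in enumerate(self.residue_index)}
        idx = np.array([pos[n] for n in residue_numbers])
        return self.D[np.ix_(idx, idx)]


@dataclass(frozen=True)
class GloconMatrix:
    """Symmetric chain-by-chain GLOCON scores for one segment."""

    chain_ids: tuple[str, ...]
    G: np.ndarray
    f: np.ndarray  # fraction of segment residues modeled in both chains, per pair

    def __post_init__(self):
        n = len(self.chain_ids)
        if self.G.shape != (n, n) or self.f.shape != (n, n):
            raise ValueError("matrix shapes disagree with chain_ids")

    def score(self, a: str, b: str) -> float:
        i, j = self.chain_ids.index(a), self.chain_ids.index(b)
        return float(self.G[i, j])

    @property
    def max_offdiagonal(self) -> float:
        if len(self.chain_ids) < 2:
            return 0.0
        mask = ~np.eye(len(self.chain_ids), dtype=bool)
        return float(self.G[mask].max())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.G, index=list(self.chain_ids),
                     columns=list(self.chain_ids)).to_csv(path, float_format="%.6f")

    def to_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance-matrix format for interoperability with tree tools."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.chain_ids)}\n")
            for cid, row in zip(self.chain_ids, self.G):
                name = cid[:10].ljust(10)
                fh.write(name + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def ca_distance_matrix(chain: ChainRecord) -> CaDistanceMatrix:
    """All-pairs Calpha distances of one chain, in residue-number order.

    The matrix is invariant to rotations, translations and reflections of
    the chain, which is what makes the downstream comparison
    superposition-free.
    """
    coords = chain.coords
    D = squareform(pdist(coords))
    if not np.all(np.isfinite(D)) or D.max(initial=0.0) > MAX_SANE_DISTANCE:
        raise CorruptCoordinatesError(
            f"chain {chain.key!r}: non-finite or >{MAX_SANE_DISTANCE:g} A "
            "interatomic distance"
        )
    return CaDistanceMatrix(tuple(int(n) for n in chain.residue_numbers), D)


def difference_matrix(
    a: ChainRecord, b: ChainRecord
) -> tuple[np.ndarray, list[int]]:
    """Absolute difference of two chains' distance matrices on common residues.

    Returns the |D_a - D_b| matrix indexed by the sorted list of residues
    modeled in both chains.  Raises :class:`InsufficientOverlapError` when
    fewer than three residues are shared.
    """
    common = sorted(set(a.residues) & set(b.residues))
    if len(common) < 3:
        raise InsufficientOverlapError(a.key, b.key, len(common))
    Da = ca_distance_matrix(a).subset(common)
    Db = ca_distance_matrix(b).subset(common)
    return np.abs(Da - Db), common


def apply_noise_filter(diff: np.ndarray, noise_threshold: float) -> np.ndarray:
    """Zero every element strictly below the threshold; elements at or above pass."""
    if noise_threshold < 0:
        raise ValueError("noise_threshold must be >= 0")
    out = diff.copy()
    out[out < noise_threshold] = 0.0
    return out


def fraction_modeled(a: ChainRecord, b: ChainRecord, segment: Segment) -> float:
    """Fraction of the segment interval modeled in *both* chains.

    Using the segment length as denominator makes the fraction symmetric in
    (a, b) and comparable across all pairs of one segment; any residue
    missing from either chain counts as a gap.
    """
    common = set(a.residues) & set(b.residues)
    if not common:
        raise InsufficientOverlapError(a.key, b.key, 0)
    return len(common) / segment.length


def glocon_score(
    filtered: np.ndarray,
    fraction: float,
    mode: str = "literal_product",
) -> float:
    """Condense a filtered difference matrix into a single dissimilarity.

    ``literal_product``: sum of upper-triangle elements times ``fraction``.
    ``mean_then_fraction``: upper-triangle mean times ``fraction``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"mode must be one of {NORMALIZATION_MODES}")
    n = filtered.shape[0]
    iu = np.triu_indices(n, k=1)
    total = float(filtered[iu].sum())
    if mode == "mean_then_fraction":
        n_pairs = len(iu[0])
        total = total / n_pairs if n_pairs else 0.0
    return total * fraction


def pair_glocon(
    a: ChainRecord,
    b: ChainRecord,
    segment: Segment,
    params: GloconParams | None = None,
) -> tuple[float, float]:
    """GLOCON score and modeled fraction for one unordered chain pair."""
    params = params or GloconParams()
    diff, _ = difference_matrix(a, b)
    filtered = apply_noise_filter(diff, params.noise_threshold)
    f = fraction_modeled(a, b, segment)
    return glocon_score(filtered, f, params.normalization_mode), f


def pairwise_glocon(segment: Segment, params: GloconParams | None = None) -> GloconMatrix:
    """Full symmetric GLOCON matrix over a segment's chains.

    Each unordered pair is computed once.  Any pair with insufficient
    residue overlap fails the whole segment (the error lists the offending
    pairs); scores are never imputed.
    """
    params = params or GloconParams()
    members = segment.members
    if len(members) < 2:
        raise ValueError(f"segment {segment.segment_id!r}: need >= 2 chains to compare")
    n = len(members)
    G = np.zeros((n, n))
    F = np.eye(n)
    failures = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s, f = pair_glocon(members[i], members[j], segment, params)
            except InsufficientOverlapError as exc:
                failures.append(exc)
                continue
            G[i, j] = G[j, i] = s
            F[i, j] = F[j, i] = f
    if failures:
        raise SegmentScoreError(segment.segment_id, failures)
    return GloconMatrix(tuple(m.key for m in members), G, F)
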