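"""Exception hierarchy for the conformational-state pipeline.

Every failure mode that a caller may want to isolate per segment or per
chain pair has its own class, so the pipeline layer can report precisely
which input caused a problem.
"""


class GloconError(Exception):
    """Base class for all package errors."""


class StructureParseError(GloconError):
    """A coordinate file could not be read or contained no usable models."""


class ChainNotFoundError(GloconError):
    """The requested chain id is absent from the structure."""


class ChainTooShortError(GloconError):
    """Fewer than three Calpha positions survive extraction or filtering."""


class InsertionCodeError(GloconError):
    """Insertion-coded residues found but no explicit per-residue mapping given.

    A plain integer offset cannot express insertion codes; renumbering
    silently would corrupt the residue pairing, so this is a hard error
    unless the caller supplies a per-residue mapping.
    """


class MappingError(GloconError):
    """A chain has no row in the mapping table, or a row is malformed."""


class InsufficientOverlapError(GloconError):
    """Two chains share fewer than three reference residues."""

    def __init__(self, chain_a: str, chain_b: str, n_common: int):
        self.chain_a = chain_a
        self.chain_b = chain_b
        self.n_common = n_common
        super().__init__(
            f"insufficient overlap between {chain_a!r} and {chain_b!r}: "
            f"{n_common} common residues (need >= 3)"
        )


class SegmentScoreError(GloconError):
    """A whole-segment score computation failed for one or more chain pairs."""

    def __init__(self, segment_id: str, pair_errors):
        self.segment_id = segment_id
        self.pair_errors = list(pair_errors)
        pairs = ", ".join(f"({e.chain_a}, {e.chain_b})" for e in self.pair_errors)
        super().__init__(
            f"segment {segment_id!r}: {len(self.pair_errors)} chain pair(s) "
            f"could not be scored: {pairs}"
        )


class DegenerateGeometryError(GloconError):
    """Point set is collinear (or worse): rigid superposition is ill-posed."""


class CorruptCoordinatesError(GloconError):
    """Non-finite or absurdly large (>1e4 A) interatomic distances."""
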