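"""Reading and writing macromolecular coordinates as Calpha chain records.

The whole pipeline consumes only alpha-carbon positions indexed by
*reference-sequence* residue numbers (UniProt-style, 1-based).  This module
turns mmCIF / legacy PDB files into :class:`ChainRecord` objects via a
user-supplied mapping table (the same role SIFTS plays for the PDB archive)
and writes superposed Calpha traces back out as mmCIF.

Parsing is delegated to :mod:`gemmi`; this module owns the chain-to-reference
renumbering, alt-location resolution, and the first-model rule for
multi-model (NMR-style) inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    ChainNotFoundError,
    ChainTooShortError,
    InsertionCodeError,
    MappingError,
    StructureParseError,
)

MIN_RESIDUES = 3

_FORMATS = {
    "auto": gemmi.CoorFormat.Detect,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "pdb": gemmi.CoorFormat.Pdb,
}


@dataclass(frozen=True)
class ChainRecord:
    """One polypeptide chain's Calpha trace in reference-sequence numbering.

    Parameters
    ----------
    structure_id : str
        Identifier of the parent structure (PDB-style code or any label).
    chain_id : str
        Chain identifier within the structure.
    accession : str
        Reference-sequence (UniProt-style) accession the chain maps to.
    residues : mapping of int to (3,) float array
        Calpha position per reference residue number, in angstroms.
        Keys must be strictly increasing 1-based integers.
    source_model : int
        Model number the coordinates were taken from (1 for single-model
        files; the first model for NMR-style ensembles).
    """

    structure_id: str
    chain_id: str
    accession: str
    residues: dict[int, np.ndarray]
    source_model: int = 1

    def __post_init__(self):
        if len(self.residues) < MIN_RESIDUES:
            raise ChainTooShortError(
                f"chain {self.key!r} too short: {len(self.residues)} residues "
                f"(need >= {MIN_RESIDUES})"
            )
        nums = list(self.residues)
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(f"chain {self.key!r}: residue numbers not strictly increasing")
        clean: dict[int, np.ndarray] = {}
        for num, pos in self.residues.items():
            arr = np.asarray(pos, dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"chain {self.key!r} residue {num}: position is not a 3-vector")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"chain {self.key!r} residue {num}: non-finite coordinates")
            clean[num] = arr
        object.__setattr__(self, "residues", clean)

    @property
    def key(self) -> str:
        """Globally unique chain identifier, ``structure_id + '_' + chain_id``."""
        return f"{self.structure_id}_{self.chain_id}"

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.fromiter(self.residues, dtype=int)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) Calpha coordinates in residue-number order."""
        return np.vstack(list(self.residues.values()))

    def coords_for(self, residue_numbers: Sequence[int]) -> np.ndarray:
        return np.vstack([self.residues[n] for n in residue_numbers])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChainRecord":
        """Return a copy with every Calpha mapped through ``R x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        moved = {n: R @ p + t for n, p in self.residues.items()}
        return ChainRecord(self.structure_id, self.chain_id, self.accession,
                           moved, self.source_model)


@dataclass(frozen=True)
class MappingRow:
    structure_id: str
    chain_id: str
    accession: str
    ref_start: int
    ref_end: int
    offset: int

    def __post_init__(self):
        if self.ref_start > self.ref_end:
            raise MappingError(
                f"mapping row {self.structure_id}_{self.chain_id}: "
                f"ref_start {self.ref_start} > ref_end {self.ref_end}"
            )


class MappingTable:
    """Chain-to-reference-sequence mapping (SIFTS-style, user supplied).

    TSV columns: structure_id, chain_id, accession, ref_start, ref_end,
    offset.  The offset is added to author residue numbers to obtain
    reference numbers.  (structure_id, chain_id) pairs must be unique.
    """

    def __init__(self, rows: Iterable[MappingRow]):
        self._rows: dict[tuple[str, str], MappingRow] = {}
        for row in rows:
            k = (row.structure_id, row.chain_id)
            if k in self._rows:
                raise MappingError(f"duplicate mapping row for {k}")
            self._rows[k] = row

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows.values())

    def get(self, structure_id: str, chain_id: str) -> MappingRow:
        try:
            return self._rows[(structure_id, chain_id)]
        except KeyError:
            raise MappingError(
                f"no mapping row for structure {structure_id!r} chain {chain_id!r}"
            ) from None

    def has(self, structure_id: str, chain_id: str) -> bool:
        return (structure_id, chain_id) in self._rows

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MappingTable":
        df = pd.read_csv(path, sep="\t", dtype={"structure_id": str, "chain_id": str,
                                                "accession": str})
        required = ["structure_id", "chain_id", "accession", "ref_start", "ref_end", "offset"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise MappingError(f"mapping table {path}: missing columns {missing}")
        rows = [
            MappingRow(r.structure_id, r.chain_id, r.accession,
                       int(r.ref_start), int(r.ref_end), int(r.offset))
            for r in df.itertuples()
        ]
        return cls(rows)

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(r.structure_id, r.chain_id, r.accession, r.ref_start, r.ref_end, r.offset)
             for r in self],
            columns=["structure_id", "chain_id", "accession", "ref_start", "ref_end", "offset"],
        )
        df.to_csv(path, sep="\t", index=False)


def read_structure(path: str | Path, format: str = "auto") -> gemmi.Structure:
    """Parse an mmCIF or legacy PDB file into a gemmi structure handle.

    ``format`` is one of ``mmcif``, ``pdb``, ``auto`` (detect from content
    and extension).  Raises :class:`StructureParseError` on unreadable input
    or a structure with no models or no chains.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_FORMATS)}")
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or all(len(model) == 0 for model in st):
        raise StructureParseError(f"{path}: structure contains no chains")
    st.setup_entities()
    return st


def select_model(handle: gemmi.Structure, policy: str = "first") -> gemmi.Structure:
    """Reduce a (possibly multi-model) structure to a single model.

    NMR-style ensembles are represented by the first model *in file order*,
    regardless of model numbering.  Single-model structures pass through
    unchanged.  The input handle is not modified.
    """
    if policy != "first":
        raise ValueError(f"unknown model-selection policy {policy!r}")
    if len(handle) == 0:
        raise StructureParseError("structure contains no models")
    out = handle.clone()
    while len(out) > 1:
        del out[1]
    return out


def _resolve_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by lexicographically smallest altloc
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def extract_chain(
    handle: gemmi.Structure,
    chain_id: str,
    mapping: MappingRow,
    residue_map: Optional[Mapping[tuple[int, str], int]] = None,
) -> ChainRecord:
    """Extract one chain's Calpha trace, renumbered into reference coordinates.

    Only residues with a carbon atom named CA are kept (waters, ligands and
    Calpha-less residues are treated as unmodeled).  Author residue numbers
    are shifted by ``mapping.offset``; residues falling outside
    ``[ref_start, ref_end]`` are dropped.  Alt-locations are resolved to the
    highest-occupancy conformer (ties to the smallest altloc id).

    Insertion-coded residues cannot be expressed by a plain offset: they are
    an error unless ``residue_map`` gives an explicit
    ``(author_number, insertion_code) -> reference_number`` entry per residue.
    """
    model = select_model(handle)[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(
            f"chain {chain_id!r} not found in structure {handle.name!r} "
            f"(present: {[c.name for c in model]})"
        )
    residues: dict[int, np.ndarray] = {}
    for res in chain:
        if res.is_water():
            continue
        cas = [a for a in res if a.name == "CA" and a.element == gemmi.Element("C")]
        if not cas:
            continue
        icode = res.seqid.icode if res.seqid.icode.strip() else ""
        if icode and residue_map is None:
            raise InsertionCodeError(
                f"{handle.name}/{chain_id}: residue {res.seqid.num}{icode} carries an "
                "insertion code; supply an explicit residue_map to place it"
            )
        if residue_map is not None:
            try:
                ref_num = residue_map[(res.seqid.num, icode)]
            except KeyError:
                if icode:
                    raise InsertionCodeError(
                        f"{handle.name}/{chain_id}: residue {res.seqid.num}{icode} "
                        "missing from residue_map"
                    ) from None
                ref_num = res.seqid.num + mapping.offset
        else:
            ref_num = res.seqid.num + mapping.offset
        if not (mapping.ref_start <= ref_num <= mapping.ref_end):
            continue
        atom = _resolve_altloc(cas)
        residues[ref_num] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    if len(residues) < MIN_RESIDUES:
        raise ChainTooShortError(
            f"chain too short: {handle.name}/{chain_id} has {len(residues)} mapped "
            f"Calpha residues after filtering (need >= {MIN_RESIDUES})"
        )
    residues = dict(sorted(residues.items()))
    model_num = handle[0].num
    return ChainRecord(mapping.structure_id, chain_id, mapping.accession,
                       residues, source_model=model_num)


_IDENTITY = (np.eye(3), np.zeros(3))


def chains_to_structure(
    records: Sequence[ChainRecord],
    transforms: Optional[Sequence[Optional[tuple[np.ndarray, np.ndarray]]]] = None,
    name: str = "superposed",
) -> gemmi.Structure:
    """Assemble Calpha-only chain records into one gemmi structure.

    Each record becomes its own model (numbered 1..n in input order) so that
    overlapping superposed copies remain individually addressable.  Residues
    are written as alanine Calpha atoms carrying the reference numbering.
    """
    if transforms is None:
        transforms = [None] * len(records)
    if len(transforms) != len(records):
        raise ValueError("one transform (or None) required per record")
    st = gemmi.Structure()
    st.name = name
    for i, (rec, tr) in enumerate(zip(records, transforms), start=1):
        R, t = tr if tr is not None else _IDENTITY
        model = gemmi.Model(i)
        chain = gemmi.Chain(rec.chain_id or "A")
        for num, pos in rec.residues.items():
            x = np.asarray(R, dtype=float) @ pos + np.asarray(t, dtype=float)
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(num), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.pos = gemmi.Position(*x)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_superposed(
    records: Sequence[ChainRecord],
    transforms: Optional[Sequence[Optional[tuple[np.ndarray, np.ndarray]]]],
    path: str | Path,
) -> None:
    """Write transformed chain records to an mmCIF file (one model per chain).

    Re-reading the file reproduces the transformed Calpha positions to the
    mmCIF coordinate precision (1e-3 A).
    """
    for tr in transforms or []:
        if tr is None:
            continue
        R, _ = tr
        R = np.asarray(R, dtype=float)
        if not math.isclose(abs(float(np.linalg.det(R))), 1.0, abs_tol=1e-6):
            raise ValueError("transform rotation is not a rigid motion (|det| != 1)")
    st = chains_to_structure(records, transforms, name=Path(path).stem)
    path = Path(path)
    try:
        st.make_mmcif_document().write_file(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
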