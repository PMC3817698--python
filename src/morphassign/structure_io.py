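"""Internal atomic data model and PDB / FASTA input-output.

The working model is a plain hierarchy of chains, residues and atoms in
orthogonal Å coordinates (the frame of the density map).  Two optional
per-residue integers travel with a residue through every stage:

``template_index``
    The residue's position in the original template chain.  It survives
    trimming and is what the segment-order constraint of the sequence
    assignment compares.  Persisted in PDB files through ``REMARK  99``
    records so the constraint survives a round trip to disk.

``truth_index``
    Ground-truth target-sequence position (0-based), set only by the
    synthetic-case generator so benchmarks can score assignments.  ``None``
    for real data.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np
from Bio import SeqIO

from .constants import AA3_TO_1, ALLOWED_SEQ_CHARS, CHAIN_BREAK_CUTOFF
from .errors import EmptyModelError, FormatError

__all__ = [
    "Atom", "Residue", "Chain", "AtomicModel", "TargetSequence",
    "read_model", "write_model", "read_sequence", "contiguous_runs",
]


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray          # (3,) Å
    b: float = 20.0          # isotropic B factor, Å²
    occ: float = 1.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)

    @property
    def electrons(self) -> float:
        """Electron count scaled by occupancy (the rasterisation weight)."""
        return gemmi.Element(self.element).atomic_number * self.occ


@dataclass
class Residue:
    seqid: int
    name: str                           # 3-letter code
    atoms: list[Atom] = field(default_factory=list)
    template_index: int | None = None
    truth_index: int | None = None
    assigned_pos: int | None = None     # 0-based target-sequence position

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    def centroid(self) -> np.ndarray:
        return np.mean([a.pos for a in self.atoms], axis=0)

    def translate(self, vec: np.ndarray) -> None:
        for a in self.atoms:
            a.pos = a.pos + vec


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class AtomicModel:
    chains: list[Chain] = field(default_factory=list)

    def residues(self) -> Iterator[tuple[Chain, Residue]]:
        for ch in self.chains:
            for res in ch.residues:
                yield ch, res

    @property
    def n_residues(self) -> int:
        return sum(len(ch.residues) for ch in self.chains)

    def atoms(self) -> Iterator[Atom]:
        for _, res in self.residues():
            yield from res.atoms

    def coords(self) -> np.ndarray:
        pts = [a.pos for a in self.atoms()]
        return np.array(pts) if pts else np.empty((0, 3))

    def copy(self) -> "AtomicModel":
        return _copy.deepcopy(self)

    def validate(self) -> None:
        """Raise FormatError if a structural invariant is violated."""
        if self.n_residues == 0:
            raise EmptyModelError("model has no residues")
        for ch in self.chains:
            nums = [r.seqid for r in ch.residues]
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise FormatError(
                    f"residue numbers not strictly increasing in chain {ch.id}")
            tidx = [r.template_index for r in ch.residues
                    if r.template_index is not None]
            if any(b <= a for a, b in zip(tidx, tidx[1:])):
                raise FormatError(
                    f"template_index not strictly increasing in chain {ch.id}")
            for r in ch.residues:
                if sum(1 for a in r.atoms if a.name == "CA") > 1:
                    raise FormatError(
                        f"residue {ch.id}/{r.seqid} has multiple CA atoms")


def contiguous_runs(chain: Chain,
                    break_cutoff: float = CHAIN_BREAK_CUTOFF) -> list[list[Residue]]:
    """Split a chain into runs unbroken by numbering gaps or CA-CA jumps.

    A break occurs where residue numbering jumps by more than one or where
    the CA-CA distance of successive residues exceeds ``break_cutoff`` Å.
    """
    runs: list[list[Residue]] = []
    cur: list[Residue] = []
    for res in chain.residues:
        if cur:
            prev = cur[-1]
            broken = res.seqid != prev.seqid + 1
            if not broken and prev.ca is not None and res.ca is not None:
                broken = np.linalg.norm(res.ca.pos - prev.ca.pos) > break_cutoff
            if broken:
                runs.append(cur)
                cur = []
        cur.append(res)
    if cur:
        runs.append(cur)
    return runs


# --------------------------------------------------------------------------
# PDB I/O (via gemmi)
# --------------------------------------------------------------------------

_REMARK_TAG = "REMARK  99"


def _parse_remarks(raw_remarks: list[str]) -> dict[tuple[str, int], dict]:
    """Extract per-residue provenance from REMARK 99 records."""
    out: dict[tuple[str, int], dict] = {}
    for line in raw_remarks:
        parts = line.split()
        if len(parts) >= 6 and parts[0] == "REMARK" and parts[1] == "99" and \
                parts[2] in ("TMPLIDX", "TRUTHIDX"):
            key = (parts[3], int(parts[4]))
            out.setdefault(key, {})[parts[2]] = int(parts[5])
    return out


def read_model(path: str | Path) -> AtomicModel:
    """Read a protein model from a PDB file.

    Waters and non-protein heteroatoms are dropped; alternate locations are
    collapsed to the highest-occupancy conformer.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"no models in {path}")
    prov = _parse_remarks(list(st.raw_remarks))

    model = AtomicModel()
    for gch in st[0]:
        ch = Chain(gch.name)
        for gres in gch:
            if gres.name not in AA3_TO_1 and gres.name != "UNK":
                continue  # waters, ligands, nucleic acids
            res = Residue(seqid=gres.seqid.num, name=gres.name)
            # collapse altlocs: keep highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for ga in gres:
                cur = best.get(ga.name)
                if cur is None or ga.occ > cur.occ:
                    best[ga.name] = ga
            for ga in best.values():
                res.atoms.append(Atom(
                    name=ga.name, element=ga.element.name,
                    pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    b=ga.b_iso, occ=ga.occ))
            meta = prov.get((ch.id, res.seqid))
            if meta:
                if "TMPLIDX" in meta:
                    res.template_index = meta["TMPLIDX"]
                if "TRUTHIDX" in meta:
                    res.truth_index = meta["TRUTHIDX"]
            if res.atoms:
                ch.residues.append(res)
        if ch.residues:
            model.chains.append(ch)
    if model.n_residues == 0:
        raise EmptyModelError(f"no protein residues in {path}")
    model.validate()
    return model


def write_model(model: AtomicModel, path: str | Path) -> None:
    """Write a model as PDB; provenance indices go into REMARK 99 records."""
    if model.n_residues == 0:
        raise EmptyModelError("refusing to write an empty model")
    st = gemmi.Structure()
    st.name = "morphassign"
    st.cell = gemmi.UnitCell(1, 1, 1, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    remarks: list[str] = []
    for ch in model.chains:
        gch = gemmi.Chain(ch.id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqid, " ")
            gres.het_flag = "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.b_iso = a.b
                ga.occ = a.occ
                gres.add_atom(ga)
            gch.add_residue(gres)
            if res.template_index is not None:
                remarks.append(
                    f"{_REMARK_TAG} TMPLIDX {ch.id} {res.seqid} {res.template_index}")
            if res.truth_index is not None:
                remarks.append(
                    f"{_REMARK_TAG} TRUTHIDX {ch.id} {res.seqid} {res.truth_index}")
        gm.add_chain(gch)
    st.add_model(gm)
    st.raw_remarks = remarks
    st.write_pdb(str(path))


# --------------------------------------------------------------------------
# Sequences
# --------------------------------------------------------------------------

@dataclass
class TargetSequence:
    sequence: str
    ncs_copies: int = 1

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - ALLOWED_SEQ_CHARS
        if bad:
            raise FormatError(
                f"illegal sequence characters: {''.join(sorted(bad))}")
        if self.ncs_copies < 1:
            raise ValueError("ncs_copies must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    def __getitem__(self, item):
        return self.sequence[item]


def read_sequence(path: str | Path, ncs_copies: int = 1) -> TargetSequence:
    """Read the first record of a FASTA file as the target sequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return TargetSequence(str(records[0].seq), ncs_copies=ncs_copies)


def write_sequence(seq: TargetSequence, path: str | Path,
                   name: str = "target") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        s = seq.sequence
        for i in range(0, len(s), 60):
            fh.write(s[i:i + 60] + "\n")
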