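"""Reading and writing the standard formats the tool touches.

Structures come in as PDB or mmCIF files following the AlphaFold convention:
one polymer chain, per-residue model confidence (pLDDT, 0-100) stored in the
B-factor column.  Experimental structures are accepted too; their B-factors
are then treated as a pLDDT stand-in, which callers should keep in mind when
interpreting the confidence feature.

Phosphorylation-site annotations arrive as UTF-8 TSV tables in the style of
PhosphoSitePlus regulatory/disease exports (columns: accession, position,
residue, annotations).  Positions are 1-based throughout (UniProt
convention); they are converted to 0-based only inside algorithms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
import biotite.structure.io.pdbx as pdbx_io

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHO_RESIDUES = frozenset("STY")
ANNOTATION_DELIMITER = ";"

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues map to X and are excluded as site candidates
    "SEP": "X", "TPO": "X", "PTR": "X", "MSE": "X", "CSO": "X",
}

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureError(ValueError):
    """Raised for unreadable or empty structure files."""


class SiteTableError(ValueError):
    """Raised for malformed rows in a site annotation table."""


@dataclass
class ProteinRecord:
    """A single-chain protein: sequence, Cα trace, sidechain centers, pLDDT.

    ``sidechain_centers`` rows are NaN where the residue has no sidechain
    heavy atoms (glycine, or missing density).
    """

    accession: str
    sequence: str
    ca_coords: np.ndarray          # (L, 3) Å
    sidechain_centers: np.ndarray  # (L, 3) Å, NaN rows where absent
    plddt: np.ndarray              # (L,) in [0, 100]

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.sidechain_centers = np.asarray(self.sidechain_centers, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        L = len(self.sequence)
        if self.ca_coords.shape != (L, 3):
            raise ValueError(
                f"{self.accession}: ca_coords shape {self.ca_coords.shape} "
                f"does not match sequence length {L}"
            )
        if self.sidechain_centers.shape != (L, 3):
            raise ValueError(f"{self.accession}: sidechain_centers shape mismatch")
        if self.plddt.shape != (L,):
            raise ValueError(f"{self.accession}: plddt length mismatch")
        if L and (np.nanmin(self.plddt) < 0 or np.nanmax(self.plddt) > 100):
            raise ValueError(f"{self.accession}: pLDDT outside [0, 100]")
        if L > 1:
            steps = np.linalg.norm(np.diff(self.ca_coords, axis=0), axis=1)
            if np.any(steps <= 0):
                raise ValueError(f"{self.accession}: zero-length Cα step")

    def __len__(self) -> int:
        return len(self.sequence)

    def has_sidechain(self, index: int) -> bool:
        return bool(np.all(np.isfinite(self.sidechain_centers[index])))

    def residue_at(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.sequence[position - 1]


@dataclass
class SiteRecord:
    """One phosphorylation site on a protein."""

    accession: str
    position: int                      # 1-based
    residue: str                       # S/T/Y
    annotations: list[str] = field(default_factory=list)
    functional_label: int | None = None
    regulatory_label: str | None = None  # "induced" | "inhibited"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise SiteTableError(
                f"{self.accession}: position {self.position} violates the "
                "1-based convention"
            )
        if self.residue not in PHOSPHO_RESIDUES:
            raise SiteTableError(
                f"{self.accession}:{self.position}: residue {self.residue!r} "
                "is not S/T/Y"
            )
        if self.regulatory_label not in (None, "induced", "inhibited"):
            raise ValueError(f"bad regulatory_label {self.regulatory_label!r}")


@dataclass
class PredictionRow:
    """A scored site; the positive class requires score strictly above 0.5."""

    accession: str
    position: int
    residue: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def predicted_class(self) -> int:
        # ties at exactly 0.5 fall to the negative / inhibited class
        return int(self.score > 0.5)


def check_site_consistency(site: SiteRecord, protein: ProteinRecord) -> bool:
    """True iff the site's residue letter matches the protein sequence."""
    if site.position > len(protein):
        return False
    return protein.residue_at(site.position) == site.residue


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> ProteinRecord:
    """Read a PDB/mmCIF file into a :class:`ProteinRecord`.

    The first polymer chain is used (with a warning if the file has more);
    pLDDT is taken from the B-factor column; non-standard residues become X.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in {".cif", ".mmcif", ".pdbx"}:
            cif = pdbx_io.CIFFile.read(str(path))
            atoms = pdbx_io.get_structure(cif, model=1, extra_fields=["b_factor"])
        else:
            pdb = pdb_io.PDBFile.read(str(path))
            atoms = pdb.get_structure(model=1, extra_fields=["b_factor"])
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise StructureError(f"cannot parse structure file {path}: {exc}") from exc

    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise StructureError(f"{path}: no amino-acid atoms found")
    chains = np.unique(atoms.chain_id)
    if len(chains) > 1:
        warnings.warn(
            f"{path.name}: {len(chains)} chains found, using first "
            f"({chains[0]!r})", stacklevel=2,
        )
    atoms = atoms[atoms.chain_id == chains[0]]

    accession = path.stem
    sequence: list[str] = []
    ca_rows: list[np.ndarray] = []
    sc_rows: list[np.ndarray] = []
    plddt: list[float] = []
    for residue in struc.residue_iter(atoms):
        ca_mask = residue.atom_name == "CA"
        if not ca_mask.any():
            continue
        ca = residue[ca_mask][0]
        letter = _THREE_TO_ONE.get(str(ca.res_name).upper(), "X")
        sc_mask = ~np.isin(residue.atom_name, list(_BACKBONE_ATOMS)) & (
            residue.element != "H"
        )
        if sc_mask.any():
            sc_rows.append(residue.coord[sc_mask].mean(axis=0))
        else:
            sc_rows.append(np.full(3, np.nan))
        sequence.append(letter)
        ca_rows.append(np.asarray(ca.coord, dtype=float))
        plddt.append(float(ca.b_factor))
    if not ca_rows:
        raise StructureError(f"{path}: chain has no Cα atoms")
    return ProteinRecord(
        accession=accession,
        sequence="".join(sequence),
        ca_coords=np.array(ca_rows),
        sidechain_centers=np.array(sc_rows),
        plddt=np.array(plddt),
    )


def write_structure(protein: ProteinRecord, path: str | Path) -> None:
    """Write a Cα + sidechain-pseudo-atom PDB file, pLDDT in the B column.

    Used by the synthetic generator; real mmCIF writing is out of scope.
    """
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items() if v != "X"}
    n_atoms = len(protein) + int(np.isfinite(protein.sidechain_centers).all(axis=1).sum())
    arr = struc.AtomArray(n_atoms)
    arr.add_annotation("b_factor", dtype=float)
    i = 0
    for res_idx in range(len(protein)):
        res_name = one_to_three.get(protein.sequence[res_idx], "UNK")
        for atom_name, coord in (
            ("CA", protein.ca_coords[res_idx]),
            ("CB", protein.sidechain_centers[res_idx]),
        ):
            if atom_name == "CB" and not protein.has_sidechain(res_idx):
                continue
            arr.coord[i] = coord
            arr.chain_id[i] = "A"
            arr.res_id[i] = res_idx + 1
            arr.res_name[i] = res_name
            arr.atom_name[i] = atom_name
            arr.element[i] = "C"
            arr.hetero[i] = False
            arr.b_factor[i] = protein.plddt[res_idx]
            i += 1
    pdb = pdb_io.PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Accession → sequence mapping from a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# site tables and predictions
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = ("accession", "position", "residue", "annotations")
PREDICTION_COLUMNS = ("accession", "position", "residue", "score", "predicted_class")


def read_site_table(
    path: str | Path, delimiter: str = ANNOTATION_DELIMITER
) -> list[SiteRecord]:
    """Parse a PSP-style TSV of phosphorylation sites.

    Malformed positions raise :class:`SiteTableError` with the line number.
    """
    sites: list[SiteRecord] = []
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        missing = set(SITE_TABLE_COLUMNS) - set(header)
        if missing:
            raise SiteTableError(f"{path}: missing columns {sorted(missing)}")
        idx = {name: header.index(name) for name in SITE_TABLE_COLUMNS}
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            raw_pos = fields[idx["position"]]
            try:
                position = int(raw_pos)
            except ValueError as exc:
                raise SiteTableError(
                    f"{path}:{lineno}: position {raw_pos!r} is not an integer"
                ) from exc
            raw_ann = fields[idx["annotations"]] if idx["annotations"] < len(fields) else ""
            annotations = [a.strip() for a in raw_ann.split(delimiter) if a.strip()]
            try:
                sites.append(
                    SiteRecord(
                        accession=fields[idx["accession"]],
                        position=position,
                        residue=fields[idx["residue"]],
                        annotations=annotations,
                    )
                )
            except SiteTableError as exc:
                raise SiteTableError(f"{path}:{lineno}: {exc}") from exc
    return sites


def write_site_table(
    sites: Iterable[SiteRecord], path: str | Path,
    delimiter: str = ANNOTATION_DELIMITER,
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(SITE_TABLE_COLUMNS + ("functional_label", "regulatory_label")) + "\n")
        for s in sites:
            handle.write(
                "\t".join(
                    [
                        s.accession,
                        str(s.position),
                        s.residue,
                        delimiter.join(s.annotations),
                        "" if s.functional_label is None else str(s.functional_label),
                        "" if s.regulatory_label is None else s.regulatory_label,
                    ]
                )
                + "\n"
            )


def write_predictions(rows: Sequence[PredictionRow], path: str | Path) -> None:
    """Write predictions as TSV; scores printed with 6 decimals."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for row in rows:
            handle.write(
                f"{row.accession}\t{row.position}\t{row.residue}\t"
                f"{row.score:.6f}\t{row.predicted_class}\n"
            )


def read_predictions(path: str | Path) -> list[PredictionRow]:
    rows: list[PredictionRow] = []
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != PREDICTION_COLUMNS:
            raise ValueError(f"{path}: unexpected prediction header {header}")
        for line in handle:
            acc, pos, res, score, _cls = line.rstrip("\n").split("\t")
            rows.append(PredictionRow(acc, int(pos), res, float(score)))
    return rows
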