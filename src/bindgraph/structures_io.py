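"""Protein structure input/output and ligand-proximity binding labels.

Reads PDB files into per-chain alpha-carbon traces, extracts ligand atom
sets, and derives per-residue binding labels from spatial proximity to the
ligand (a residue is *binding* when any of its considered atoms lies within
a radius of any ligand atom; 10 Angstrom is the conventional pocket
definition). Chains are plain dataclasses so that synthetic and experimental
structures flow through identical code paths.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

__all__ = [
    "ProteinChain",
    "LigandAtoms",
    "parse_structure",
    "extract_ligand",
    "label_binding_residues",
    "write_chain_pdb",
    "write_labels_tsv",
    "read_labels_tsv",
    "write_fasta",
]

#: three-letter -> one-letter codes for the 20 standard amino acids
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"

#: common modified residues mapped to their standard parent one-letter code;
#: anything polymeric not found here or in THREE_TO_ONE becomes 'X'
MODIFIED_PARENT = {
    "MSE": "M",  # selenomethionine
    "SEP": "S",  # phosphoserine
    "TPO": "T",  # phosphothreonine
    "PTR": "Y",  # phosphotyrosine
    "CSO": "C",  # S-hydroxycysteine
    "CME": "C",
    "MLY": "K",  # N-dimethyl-lysine
    "HYP": "P",  # hydroxyproline
    "KCX": "K",
    "CSD": "C",
    "SEC": "C",  # selenocysteine: closest standard parent
    "PCA": "E",  # pyroglutamate
    "FME": "M",
}

_WATER = {"HOH", "WAT", "DOD"}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ProteinChain:
    """One polypeptide chain: sequence, CA trace, optional binding labels.

    ``sequence[i]``, ``ca_coords[i]``, ``labels[i]`` and
    ``residue_numbers[i]`` all refer to the same residue; indexing is
    0-based and PDB residue numbers are metadata only.
    """

    chain_id: str
    sequence: str
    ca_coords: np.ndarray  # (L, 3) Angstrom
    labels: np.ndarray | None = None  # (L,) int, 1 = binding
    residue_numbers: list[int] | None = None
    #: per-residue heavy-atom coordinate arrays (incl. side chains) when the
    #: source structure had them; enables all-atom pocket labelling
    residue_atoms: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must be an (L, 3) matrix")
        if len(self.sequence) != self.ca_coords.shape[0]:
            raise ValueError(
                f"sequence length {len(self.sequence)} != "
                f"{self.ca_coords.shape[0]} coordinate rows"
            )
        if not np.isfinite(self.ca_coords).all():
            raise ValueError("non-finite coordinates")
        bad = set(self.sequence) - set(AA_ALPHABET + "X")
        if bad:
            raise ValueError(f"invalid sequence letters: {sorted(bad)}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.sequence),):
                raise ValueError("labels length does not match sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LigandAtoms:
    """Heavy-atom coordinates of one bound ligand."""

    ligand_id: str
    coords: np.ndarray  # (M, 3) Angstrom

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[0] < 1 or self.coords.shape[1] != 3:
            raise ValueError("ligand needs at least one (x, y, z) atom")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite ligand coordinates")


def _as_handle(source):
    """Accept a filesystem path or raw PDB text."""
    if hasattr(source, "read"):
        return source
    text = str(source)
    if "\n" in text:  # raw PDB content
        return io.StringIO(text)
    return text


def _pick_altloc(residue, name: str):
    """Highest-occupancy conformer; ties resolved toward altloc 'A'."""
    atom = residue[name]
    if not atom.is_disordered():
        return atom
    children = sorted(
        atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def parse_structure(source, chain_selector: str) -> ProteinChain:
    """Parse one chain of a PDB file into a :class:`ProteinChain`.

    Residues lacking an alpha-carbon are skipped (a warning reports them);
    modified residues map to their standard parent letter when known,
    otherwise to ``'X'``. Hetero ligands and waters are ignored here (see
    :func:`extract_ligand`).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", _as_handle(source))
    model = next(structure.get_models())
    chains = {c.id: c for c in model}
    if chain_selector not in chains:
        raise KeyError(
            f"chain {chain_selector!r} not found; available: {sorted(chains)}"
        )
    chain = chains[chain_selector]

    letters: list[str] = []
    coords: list[np.ndarray] = []
    resnums: list[int] = []
    atoms: list[np.ndarray] = []
    skipped: list[str] = []
    for res in chain:
        resname = res.get_resname().strip()
        hetflag = res.id[0]
        if resname in THREE_TO_ONE:
            letter = THREE_TO_ONE[resname]
        elif resname in MODIFIED_PARENT:
            letter = MODIFIED_PARENT[resname]
        elif hetflag == " ":
            letter = "X"  # unrecognised polymer residue
        else:
            continue  # ligand / water / other heteroatom group
        if "CA" not in res:
            skipped.append(f"{resname}{res.id[1]}")
            continue
        ca = _pick_altloc(res, "CA")
        letters.append(letter)
        coords.append(np.asarray(ca.get_coord(), dtype=float))
        resnums.append(res.id[1])
        heavy = [
            _pick_altloc(res, a.get_name()).get_coord()
            for a in res.get_unpacked_list()
            if a.element != "H"
        ]
        atoms.append(np.asarray(heavy, dtype=float))
    if skipped:
        warnings.warn(
            f"chain {chain_selector}: skipped {len(skipped)} residue(s) "
            f"without alpha-carbon: {', '.join(skipped)}"
        )
    if not letters:
        raise ValueError(f"chain {chain_selector} has no residues with alpha-carbons")
    if isinstance(source, str) and "\n" not in source:
        from pathlib import Path

        prefix = Path(source).stem
    else:
        prefix = ""
    return ProteinChain(
        chain_id=f"{prefix}:{chain_selector}" if prefix else chain_selector,
        sequence="".join(letters),
        ca_coords=np.vstack(coords),
        residue_numbers=resnums,
        residue_atoms=atoms,
    )


def extract_ligand(source, resname: str | None = None) -> LigandAtoms:
    """Collect HETATM coordinates of one ligand from a PDB file.

    With ``resname=None`` every non-water heteroatom group is pooled into a
    single ligand (useful for single-ligand synthetic complexes).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", _as_handle(source))
    model = next(structure.get_models())
    coords = []
    names = set()
    for chain in model:
        for res in chain:
            rn = res.get_resname().strip()
            if res.id[0] == " " or rn in _WATER:
                continue
            if rn in THREE_TO_ONE or rn in MODIFIED_PARENT:
                continue  # modified residues are polymer, not ligand
            if resname is not None and rn != resname:
                continue
            names.add(rn)
            for atom in res:
                if atom.element != "H":
                    coords.append(atom.get_coord())
    if not coords:
        raise ValueError(
            f"no ligand atoms found" + (f" for residue name {resname!r}" if resname else "")
        )
    return LigandAtoms(ligand_id="+".join(sorted(names)), coords=np.asarray(coords, float))


def label_binding_residues(
    chain: ProteinChain,
    ligand: LigandAtoms,
    radius: float = 10.0,
    atom_mode: str = "auto",
) -> np.ndarray:
    """Binary binding labels: residue i is 1 iff its minimum atom-to-ligand
    distance is <= ``radius`` (Angstrom).

    ``atom_mode`` selects the residue atoms considered: ``"ca_only"`` uses
    the CA trace, ``"all_atom"`` all heavy atoms, ``"auto"`` uses all atoms
    when the chain carries them and falls back to CA otherwise.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if atom_mode not in {"auto", "ca_only", "all_atom"}:
        raise ValueError(f"unknown atom_mode {atom_mode!r}")
    if atom_mode == "auto":
        atom_mode = "all_atom" if chain.residue_atoms else "ca_only"
    if atom_mode == "all_atom" and not chain.residue_atoms:
        raise ValueError("chain has no per-residue atom records for all_atom mode")
    labels = np.zeros(len(chain), dtype=int)
    if atom_mode == "ca_only":
        dmin = cdist(chain.ca_coords, ligand.coords).min(axis=1)
        labels[dmin <= radius] = 1
    else:
        for i, atoms in enumerate(chain.residue_atoms):
            if cdist(atoms, ligand.coords).min() <= radius:
                labels[i] = 1
    return labels


# ---------------------------------------------------------------------------
# writers (PDB ATOM/HETATM fixed-column records, label TSV, FASTA)

def write_chain_pdb(chain: ProteinChain, path, ligand: LigandAtoms | None = None) -> None:
    """Write a CA-trace PDB file (plus optional ligand HETATM records).

    Coordinates are rounded to the PDB's 3-decimal column width, so a
    write/parse round trip agrees to 1e-3 Angstrom.
    """
    lines = []
    serial = 1
    resnums = chain.residue_numbers or list(range(1, len(chain) + 1))
    for i, (aa, xyz) in enumerate(zip(chain.sequence, chain.ca_coords)):
        res3 = ONE_TO_THREE[aa]
        x, y, z = xyz
        lines.append(
            f"ATOM  {serial:5d}  CA  {res3:>3s} A{resnums[i]:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    if ligand is not None:
        for j, (x, y, z) in enumerate(ligand.coords):
            lines.append(
                f"HETATM{serial:5d}  C{j % 10:<2d} LIG L{j + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_labels_tsv(chain: ProteinChain, path) -> None:
    """Two-column TSV: 0-based residue index, binary label."""
    if chain.labels is None:
        raise ValueError("chain has no labels")
    with open(path, "w") as fh:
        fh.write("residue_index\tlabel\n")
        for i, lab in enumerate(chain.labels):
            fh.write(f"{i}\t{int(lab)}\n")


def read_labels_tsv(path) -> np.ndarray:
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("residue_index"), "unexpected label file header"
        for line in fh:
            _, lab = line.split("\t")
            out.append(int(lab))
    return np.asarray(out, dtype=int)


def write_fasta(chains: list[ProteinChain], path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(f">{c.chain_id}\n{c.sequence}\n")
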