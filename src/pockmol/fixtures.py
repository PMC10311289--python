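"""Synthetic fixtures: geometrically plausible pockets and a conditioned
SMILES corpus with computable properties and pseudo docking scores.

Everything here is seeded and bit-reproducible, so the package builds and
tests without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .codec import (
    DOCKING_RULE,
    MoleculeRecord,
    PropertyRule,
    PropertySchema,
    Vocabulary,
    tokenize,
)
from .pocket_graphs import (
    AMINO_ACIDS,
    ATOMIC_MASS,
    Atom,
    PocketStructure,
    Residue,
)

_BACKBONE_ELEMENTS = ("N", "C", "C", "O")
_BACKBONE_NAMES = ("N", "CA", "C", "O")
_SIDE_ELEMENTS = ("C", "N", "O", "S")


def make_pocket_fixture(seed: int, n_residues: int = 8
                        ) -> tuple[PocketStructure, str]:
    """Helix-like pocket: rise ~1.5 A and ~100 degrees of turn per residue.

    Each residue gets the 4 backbone atoms plus 0-4 side-chain atoms, all
    within 1.5 A of the backbone trace point. Coordinates are rounded to
    PDB precision (3 decimals) so writing + re-parsing is exact.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    radius = 2.3
    residues = []
    for i in range(n_residues):
        angle = np.deg2rad(100.0 * i)
        center = np.array([radius * np.cos(angle), radius * np.sin(angle),
                           1.5 * i])
        atoms = []
        for j in range(4):
            offset = rng.normal(0, 0.5, 3)
            norm = np.linalg.norm(offset)
            if norm > 1.5:
                offset *= 1.5 / norm
            coords = np.round(center + offset, 3)
            element = _BACKBONE_ELEMENTS[j]
            atoms.append(Atom(element=element, coords=tuple(coords),
                              mass=ATOMIC_MASS[element], is_backbone=True))
        for _ in range(int(rng.integers(0, 5))):  # 4-8 atoms total
            element = _SIDE_ELEMENTS[rng.integers(0, len(_SIDE_ELEMENTS))]
            offset = rng.normal(0, 0.6, 3)
            norm = np.linalg.norm(offset)
            if norm > 1.5:
                offset *= 1.5 / norm
            coords = np.round(center + offset, 3)
            atoms.append(Atom(element=element, coords=tuple(coords),
                              mass=ATOMIC_MASS[element], is_backbone=False))
        res_type = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
        residues.append(Residue(residue_type=res_type, atoms=tuple(atoms),
                                chain_id="A", seq_id=i + 1))
    pocket = PocketStructure(residues=tuple(residues))
    return pocket, pocket_to_pdb(pocket)


def pocket_to_pdb(pocket: PocketStructure) -> str:
    """Serialize a pocket as PDB ATOM records.

    Backbone atoms are named N/CA/C/O in order (at most four per residue);
    side-chain atoms get element + serial names so backbone flags survive a
    round-trip through :func:`pockmol.pocket_graphs.parse_pocket`.
    """
    lines = []
    serial = 1
    for res in pocket.residues:
        backbone_seen = 0
        side_seen = 0
        for atom in res.atoms:
            if atom.is_backbone:
                if backbone_seen >= 4:
                    raise ValueError("more than 4 backbone atoms in a residue")
                name = _BACKBONE_NAMES[backbone_seen]
                backbone_seen += 1
            else:
                side_seen += 1
                name = f"{atom.element.upper()}{side_seen}X"[:4]
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{res.residue_type:>4s} "
                f"{res.chain_id}{res.seq_id:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element.upper():>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Conditioned corpus
# ---------------------------------------------------------------------------

@dataclass
class CorpusEntry:
    smiles: str
    hard_bit: int  # 1 iff the molecule contains nitrogen
    heavy_atoms: int
    docking_score: float
    pocket_index: int


@dataclass
class ConditionedCorpus:
    entries: list[CorpusEntry]
    pockets: list[PocketStructure]
    pocket_pdbs: list[str]


def default_schema() -> PropertySchema:
    """Affinity bit (docking <= -7.5 kcal/mol) plus heavy-atom count."""
    return PropertySchema(rules=(
        DOCKING_RULE,
        PropertyRule(name="size", kind="soft"),
    ))


def _chain_smiles(rng: np.random.Generator, length: int, with_n: bool) -> str:
    """Linear amine/alcohol/ether chain; heteroatoms never adjacent.

    with_n=True sprinkles nitrogen densely (and guarantees at least one) so
    the "contains N" bit leaves a strong statistical footprint; with_n=False
    chains carry only C and O.
    """
    atoms = ["C"] * length
    forced_n = int(rng.integers(0, length)) if with_n else -1
    for i in range(length):
        if i > 0 and atoms[i - 1] != "C":
            continue  # keep heteroatoms non-adjacent
        if i == forced_n:
            atoms[i] = "N"
        elif with_n and rng.random() < 0.3:
            atoms[i] = "N"
        elif rng.random() < 0.25:
            atoms[i] = "O"
    if with_n and "N" not in atoms:  # forced position lost to adjacency rule
        atoms[-1 if atoms[-2] == "C" else 0] = "N"
    return "".join(atoms)


def make_conditioned_corpus(seed: int, n_records: int,
                            n_pockets: int = 4,
                            pocket_residues: int = 6) -> ConditionedCorpus:
    """Seeded corpus of valid chain SMILES with a learnable affinity bit.

    The hard bit h is "contains nitrogen"; the soft value is the heavy-atom
    count; the pseudo docking score is -5 - 3*h + N(0, 0.2), so thresholding
    at -7.5 recovers h almost always. Classes are balanced.
    """
    if n_records < 20:
        raise ValueError("need at least 20 records")
    rng = np.random.default_rng(seed)
    pockets, pdbs = [], []
    for j in range(n_pockets):
        pocket, pdb_text = make_pocket_fixture(seed + 1000 * (j + 1),
                                               n_residues=pocket_residues)
        pockets.append(pocket)
        pdbs.append(pdb_text)
    entries = []
    for i in range(n_records):
        bit = i % 2
        length = int(rng.integers(3, 13))
        smiles = _chain_smiles(rng, length, with_n=bool(bit))
        if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover
            raise AssertionError(f"fixture generator emitted invalid SMILES {smiles}")
        score = -5.0 - 3.0 * bit + rng.normal(0, 0.2)
        entries.append(CorpusEntry(
            smiles=smiles,
            hard_bit=bit,
            heavy_atoms=length,
            docking_score=float(score),
            pocket_index=i % n_pockets,
        ))
    return ConditionedCorpus(entries=entries, pockets=pockets, pocket_pdbs=pdbs)


def corpus_records(corpus: ConditionedCorpus, vocab: Vocabulary,
                   schema: PropertySchema) -> list[MoleculeRecord]:
    records = []
    for e in corpus.entries:
        records.append(MoleculeRecord(
            smiles=e.smiles,
            token_ids=tokenize(e.smiles, vocab),
            y=schema.encode({"affinity": e.docking_score, "size": e.heavy_atoms}),
            docking_score=e.docking_score,
        ))
    return records


def write_corpus(corpus: ConditionedCorpus, smi_path, tsv_path):
    """SMILES line file plus TSV sidecar (smiles, properties, docking_score)."""
    with open(smi_path, "w") as fh:
        for e in corpus.entries:
            fh.write(e.smiles + "\n")
    with open(tsv_path, "w") as fh:
        fh.write("smiles\thard_bit\tsize\tdocking_score\tpocket_index\n")
        for e in corpus.entries:
            fh.write(f"{e.smiles}\t{e.hard_bit}\t{e.heavy_atoms}\t"
                     f"{e.docking_score:.4f}\t{e.pocket_index}\n")


def read_corpus(smi_path, tsv_path, pockets: list[PocketStructure],
                pocket_pdbs: list[str]) -> ConditionedCorpus:
    entries = []
    with open(tsv_path) as fh:
        header = fh.readline()
        for line in fh:
            smiles, bit, size, score, pocket_index = line.rstrip("\n").split("\t")
            entries.append(CorpusEntry(
                smiles=smiles, hard_bit=int(bit), heavy_atoms=int(size),
                docking_score=float(score), pocket_index=int(pocket_index)))
    return ConditionedCorpus(entries=entries, pockets=pockets,
                             pocket_pdbs=pocket_pdbs)
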