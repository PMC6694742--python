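"""Sequence, cleavage-site and variant I/O, and peptide-window extraction.

Cleavage sites are peptide *bonds*, identified by the 1-based index of the
residue on their N-terminal side (the P1 residue in Schechter-Berger
nomenclature): a site with ``bond == b`` is the bond between residues ``b``
and ``b + 1``.  A protein of length ``L`` therefore has exactly ``L - 1``
candidate bonds.  Windows are bond-centered: ``flank`` residues on each side
of the bond, padded with ``-`` where the protein ends, for a fixed length of
``2 * flank`` (30 at the default flank of 15).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard one-letter residue codes, in the fixed encoder order.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: Pad symbol used beyond the protein termini.
PAD = "-"

_STANDARD_SET = frozenset(STANDARD_RESIDUES)
_ALLOWED_SET = _STANDARD_SET | {PAD}


@dataclass(frozen=True)
class Protein:
    """A protein sequence over the 20 standard residues.

    A ``-`` is tolerated only when non-standard residues were deliberately
    masked at read time (see :func:`read_fasta` with ``nonstandard="mask"``).
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = [(i + 1, c) for i, c in enumerate(self.sequence) if c not in _ALLOWED_SET]
        if bad:
            pos, res = bad[0]
            raise ValueError(
                f"protein {self.id!r}: invalid residue {res!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageSite:
    """An annotated cleavage bond: cleavage between residues ``bond`` and ``bond+1``."""

    protein_id: str
    bond: int

    def __post_init__(self) -> None:
        if self.bond < 1:
            raise ValueError(
                f"site {self.protein_id}:{self.bond}: bond index must be >= 1"
            )


@dataclass(frozen=True)
class MissenseVariant:
    """A single-residue substitution at a 1-based position."""

    protein_id: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"variant {self}: ref equals alt")
        for name, res in (("ref", self.ref), ("alt", self.alt)):
            if res not in _STANDARD_SET:
                raise ValueError(f"variant {self}: {name} {res!r} is not a standard residue")
        if self.position < 1:
            raise ValueError(f"variant {self}: position must be >= 1")


@dataclass
class LabeledDataset:
    """Peptide windows with binary labels (1 = cleaved) and (protein_id, bond) provenance."""

    windows: list[str]
    labels: np.ndarray
    provenance: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.windows) == len(self.labels) == len(self.provenance)):
            raise ValueError("windows, labels and provenance must have equal length")
        if len(set(self.provenance)) != len(self.provenance):
            raise ValueError("duplicate (protein_id, bond) in dataset")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self) - self.labels.sum())

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            [self.windows[i] for i in idx],
            self.labels[idx],
            [self.provenance[i] for i in idx],
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tbond\tlabel\twindow\n")
            for (pid, bond), lab, win in zip(self.provenance, self.labels, self.windows):
                fh.write(f"{pid}\t{bond}\t{'positive' if lab else 'negative'}\t{win}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabeledDataset":
        windows, labels, prov = [], [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("protein_id"):
                raise ValueError(f"{path}: missing dataset header")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                try:
                    pid, bond, lab, win = line.split("\t")
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields") from exc
                windows.append(win)
                labels.append(1 if lab == "positive" else 0)
                prov.append((pid, int(bond)))
        return cls(windows, np.asarray(labels), prov)


def read_fasta(path: str | Path, nonstandard: str = "strict") -> list[Protein]:
    """Read a multi-record FASTA file into :class:`Protein` objects.

    Sequences are upper-cased.  ``nonstandard`` controls residues outside the
    20-letter alphabet: ``"strict"`` (default) raises naming the residue and
    its position; ``"mask"`` replaces them with the pad symbol ``-``.
    """
    if nonstandard not in ("strict", "mask"):
        raise ValueError(f"unknown nonstandard policy {nonstandard!r}")
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty FASTA file")
    first = text.lstrip().splitlines()[0]
    if not first.startswith(">"):
        lineno = 1 + text[: text.index(first)].count("\n")
        raise ValueError(f"{path}:{lineno}: malformed FASTA, expected '>' header")
    proteins: list[Protein] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if nonstandard == "mask":
            seq = "".join(c if c in _STANDARD_SET else PAD for c in seq)
        else:
            for i, c in enumerate(seq):
                if c not in _STANDARD_SET:
                    raise ValueError(
                        f"{path}: record {record.id!r}: non-standard residue "
                        f"{c!r} at position {i + 1} (use nonstandard='mask' to pad)"
                    )
        proteins.append(Protein(record.id, seq))
    if not proteins:
        raise ValueError(f"{path}: no FASTA records found")
    return proteins


def read_site_table(path: str | Path) -> list[CleavageSite]:
    """Read a tab-separated ``protein_id<TAB>bond`` site table, deduplicated in input order."""
    sites: list[CleavageSite] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'protein_id\\tbond'")
            pid, bond_s = fields
            try:
                bond = int(bond_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer bond {bond_s!r}") from exc
            if bond < 1:
                raise ValueError(f"{path}:{lineno}: bond {bond} out of range (must be >= 1)")
            key = (pid, bond)
            if key in seen:
                continue
            seen.add(key)
            sites.append(CleavageSite(pid, bond))
    return sites


def read_variant_table(path: str | Path) -> list[MissenseVariant]:
    """Read a ``protein_id<TAB>position<TAB>ref<TAB>alt`` table with exact-row dedup."""
    variants: list[MissenseVariant] = []
    seen: set[tuple[str, int, str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'protein_id\\tpos\\tref\\talt'")
            pid, pos_s, ref, alt = fields
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer position {pos_s!r}") from exc
            key = (pid, pos, ref, alt)
            if key in seen:
                continue
            seen.add(key)
            variants.append(MissenseVariant(pid, pos, ref, alt))
    return variants


def validate_variants(
    variants: Iterable[MissenseVariant], proteins: Iterable[Protein]
) -> None:
    """Check every variant's position and reference residue against its protein."""
    by_id = {p.id: p for p in proteins}
    for v in variants:
        prot = by_id.get(v.protein_id)
        if prot is None:
            raise ValueError(f"variant {v.protein_id}:{v.position}: unknown protein")
        if v.position > len(prot):
            raise ValueError(
                f"variant {v.protein_id}:{v.position}: beyond protein length {len(prot)}"
            )
        actual = prot.sequence[v.position - 1]
        if actual != v.ref:
            raise ValueError(
                f"variant {v.protein_id}:{v.position}: ref {v.ref!r} does not match "
                f"sequence residue {actual!r}"
            )


def extract_window(protein: Protein, bond: int, flank: int = 15) -> str:
    """Extract the ``2 * flank``-residue window centered on a cleavage bond.

    The window covers residues ``bond - flank + 1 .. bond`` and
    ``bond + 1 .. bond + flank``; out-of-range positions become ``-``.  The
    P1 residue always sits at window index ``flank`` (1-based).
    """
    seq = protein.sequence
    L = len(seq)
    if not 1 <= bond <= L - 1:
        raise ValueError(
            f"bond {bond} out of range [1, {L - 1}] for protein {protein.id!r}"
        )
    start = bond - flank  # 0-based slice start
    end = bond + flank
    left_pad = max(0, -start)
    right_pad = max(0, end - L)
    return PAD * left_pad + seq[max(start, 0) : min(end, L)] + PAD * right_pad


def build_dataset(
    proteins: Sequence[Protein],
    sites: Sequence[CleavageSite],
    flank: int = 15,
    negative_subsample: int | None = None,
    seed: int | None = None,
) -> LabeledDataset:
    """Assemble the labeled window dataset from proteins and annotated sites.

    Annotated bonds become positives; every other bond in the same proteins
    becomes a negative, so positives and negatives partition the ``L - 1``
    candidate bonds of each protein.  ``negative_subsample`` optionally draws
    a seeded random subset of that exhaustive negative set (training-time
    rebalancing; evaluation should normally see the full set).
    """
    by_id = {p.id: p for p in proteins}
    orphans = sorted({s.protein_id for s in sites if s.protein_id not in by_id})
    if orphans:
        raise ValueError(f"sites reference unknown proteins: {', '.join(orphans)}")
    positive_bonds: dict[str, set[int]] = {}
    for s in sites:
        prot = by_id[s.protein_id]
        if s.bond > len(prot) - 1:
            raise ValueError(
                f"site {s.protein_id}:{s.bond}: bond beyond last position "
                f"{len(prot) - 1}"
            )
        positive_bonds.setdefault(s.protein_id, set()).add(s.bond)

    windows: list[str] = []
    labels: list[int] = []
    prov: list[tuple[str, int]] = []
    neg_indices: list[int] = []
    for prot in proteins:
        pos = positive_bonds.get(prot.id, set())
        for bond in range(1, len(prot)):
            windows.append(extract_window(prot, bond, flank))
            labels.append(1 if bond in pos else 0)
            prov.append((prot.id, bond))
            if bond not in pos:
                neg_indices.append(len(windows) - 1)

    dataset = LabeledDataset(windows, np.asarray(labels), prov)
    if negative_subsample is not None and negative_subsample < len(neg_indices):
        rng = np.random.default_rng(seed)
        keep_neg = set(
            rng.choice(neg_indices, size=negative_subsample, replace=False).tolist()
        )
        keep = [
            i
            for i in range(len(dataset))
            if dataset.labels[i] == 1 or i in keep_neg
        ]
        dataset = dataset.subset(keep)
    logger.info(
        "built dataset: %d positives, %d negatives in %d proteins",
        dataset.n_positive,
        dataset.n_negative,
        len(proteins),
    )
    return dataset


def write_fasta(proteins: Iterable[Protein], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def write_site_table(sites: Iterable[CleavageSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.bond}\n")


def write_variant_table(variants: Iterable[MissenseVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        for v in variants:
            fh.write(f"{v.protein_id}\t{v.position}\t{v.ref}\t{v.alt}\n")
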