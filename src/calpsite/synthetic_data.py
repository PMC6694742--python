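"""Seeded generators for proteins with planted cleavage motifs and variant tables.

The default planted motif follows the canonical calpain subsite preferences:
Leu/Thr/Val at P2 and Lys/Tyr/Arg at P1, with a mild alanine bias in the
first two primed positions echoing the enrichment seen downstream of real
cleavage bonds.  Background residues are i.i.d. uniform over the 20 standard
residues by default (maximally interpretable for tests); a SwissProt-like
composition is available for more realistic sequences.

Positions in a :class:`MotifSpec` are offsets relative to the P1 residue:
offset 0 is P1 (the residue whose index names the bond), -1 is P2, +1 is P1'.
With ``signal_strength`` s, each motif position is overwritten by a draw
from its preference map with probability s, so s = 1 plants the motif
deterministically and s = 0 leaves sequences indistinguishable from
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence_io import (
    CleavageSite,
    LabeledDataset,
    MissenseVariant,
    Protein,
    STANDARD_RESIDUES,
    build_dataset,
)

#: Approximate SwissProt residue composition (rounded, renormalized).
SWISSPROT_COMPOSITION = {
    "A": 0.0826, "C": 0.0138, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0966,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0394, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}


def _default_preferences() -> dict[int, dict[str, float]]:
    # P2 and P1 from the canonical calpain subsite preferences; primed-side
    # alanine bias is mild (mixture with the uniform background).
    mild_a = {res: (0.24 if res == "A" else 0.76 / 19) for res in STANDARD_RESIDUES}
    return {
        -1: {"L": 0.5, "T": 0.25, "V": 0.25},  # P2
        0: {"K": 0.4, "Y": 0.3, "R": 0.3},  # P1
        1: dict(mild_a),  # P1'
        2: dict(mild_a),  # P2'
    }


@dataclass
class MotifSpec:
    """Position-specific residue preferences planted around each cleavage bond."""

    preferences: dict[int, dict[str, float]] = field(default_factory=_default_preferences)
    background: dict[str, float] | None = None  # None = uniform over 20 residues
    signal_strength: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        for offset, prefs in self.preferences.items():
            if not -15 <= offset <= 15:
                raise ValueError(f"motif offset {offset} outside ±15 of the bond")
            total = sum(prefs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"preference map at offset {offset} sums to {total}")
            for res in prefs:
                if res not in STANDARD_RESIDUES:
                    raise ValueError(f"non-standard residue {res!r} in motif")
        if self.background is not None:
            if abs(sum(self.background.values()) - 1.0) > 1e-9:
                raise ValueError("background distribution must sum to 1")

    def background_probs(self) -> np.ndarray:
        if self.background is None:
            return np.full(len(STANDARD_RESIDUES), 1.0 / len(STANDARD_RESIDUES))
        return np.array([self.background.get(r, 0.0) for r in STANDARD_RESIDUES])

    @property
    def span(self) -> tuple[int, int]:
        offs = list(self.preferences) or [0]
        return min(offs), max(offs)


def _draw(rng: np.random.Generator, probs: dict[str, float]) -> str:
    residues = list(probs)
    p = np.array([probs[r] for r in residues])
    return residues[rng.choice(len(residues), p=p / p.sum())]


def generate_proteins(
    n: int,
    length_range: tuple[int, int] = (60, 120),
    motif_spec: MotifSpec | None = None,
    sites_per_protein: int = 2,
    seed: int = 0,
) -> tuple[list[Protein], list[CleavageSite]]:
    """Generate proteins with motif-planted cleavage bonds and the ground-truth site list.

    Background residues are drawn i.i.d.; ``sites_per_protein`` bonds per
    protein are placed so motif footprints never overlap, then each motif
    position is overwritten per the spec with probability ``signal_strength``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo < 31:
        raise ValueError("minimum protein length is 31")
    if motif_spec is None:
        motif_spec = MotifSpec()
    rng = np.random.default_rng(seed)
    bg = motif_spec.background_probs()
    off_lo, off_hi = motif_spec.span
    residues = np.array(list(STANDARD_RESIDUES))

    proteins: list[Protein] = []
    sites: list[CleavageSite] = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = list(residues[rng.choice(len(residues), size=L, p=bg)])
        # candidate bonds keep the whole motif footprint inside the sequence
        bond_lo = max(1, 1 - off_lo)
        bond_hi = min(L - 1, L - off_hi)
        candidates = list(range(bond_lo, bond_hi + 1))
        span = off_hi - off_lo + 1
        if sites_per_protein * span > len(candidates):
            raise ValueError(
                f"cannot place {sites_per_protein} non-overlapping sites in a "
                f"protein of length {L}"
            )
        chosen: list[int] = []
        pool = candidates.copy()
        for _ in range(sites_per_protein):
            if not pool:
                raise ValueError("ran out of non-colliding site positions")
            b = int(pool[rng.integers(len(pool))])
            chosen.append(b)
            pool = [c for c in pool if abs(c - b) >= span]
        for bond in sorted(chosen):
            for offset, prefs in motif_spec.preferences.items():
                if rng.random() < motif_spec.signal_strength:
                    seq[bond + offset - 1] = _draw(rng, prefs)
            sites.append(CleavageSite(f"SYN{i:04d}", bond))
        proteins.append(Protein(f"SYN{i:04d}", "".join(seq)))
    return proteins, sites


def generate_variants(
    proteins: Sequence[Protein],
    sites: Sequence[CleavageSite],
    n_near: int,
    n_far: int,
    flank: int = 15,
    seed: int = 0,
) -> list[MissenseVariant]:
    """Place variants near to and far from ground-truth cleavage bonds.

    ``n_near`` positions are drawn uniformly from residues within ±flank of
    any site bond (i.e. inside some site window); ``n_far`` from residues
    outside every such window.  The reference residue is read off the
    sequence and the alternate drawn uniformly from the other 19.
    """
    rng = np.random.default_rng(seed)
    by_id = {p.id: p for p in proteins}
    near_pool: list[tuple[str, int]] = []
    far_pool: list[tuple[str, int]] = []
    site_bonds: dict[str, list[int]] = {}
    for s in sites:
        site_bonds.setdefault(s.protein_id, []).append(s.bond)
    for pid, prot in by_id.items():
        near = np.zeros(len(prot) + 1, dtype=bool)
        for bond in site_bonds.get(pid, []):
            lo = max(1, bond - flank + 1)
            hi = min(len(prot), bond + flank)
            near[lo : hi + 1] = True
        for pos in range(1, len(prot) + 1):
            (near_pool if near[pos] else far_pool).append((pid, pos))
    if n_near > 0 and not near_pool:
        raise ValueError("no near-site positions available")
    if n_far > 0 and not far_pool:
        raise ValueError("no far-from-site region exists")

    variants: list[MissenseVariant] = []
    for pool, count in ((near_pool, n_near), (far_pool, n_far)):
        for _ in range(count):
            pid, pos = pool[rng.integers(len(pool))]
            ref = by_id[pid].sequence[pos - 1]
            others = [r for r in STANDARD_RESIDUES if r != ref]
            alt = others[rng.integers(len(others))]
            variants.append(MissenseVariant(pid, pos, ref, alt))
    return variants


def generate_training_set(
    n_positive: int = 200,
    n_negative: int = 200,
    motif_spec: MotifSpec | None = None,
    flank: int = 15,
    length_range: tuple[int, int] = (60, 120),
    sites_per_protein: int = 2,
    seed: int = 0,
) -> LabeledDataset:
    """A balanced labeled window set from generated proteins.

    Generates enough proteins to supply ``n_positive`` planted bonds, builds
    the exhaustive dataset, then keeps all positives and a seeded subsample
    of ``n_negative`` motif-free bonds.
    """
    n_proteins = -(-n_positive // sites_per_protein)  # ceil
    proteins, sites = generate_proteins(
        n_proteins,
        length_range=length_range,
        motif_spec=motif_spec,
        sites_per_protein=sites_per_protein,
        seed=seed,
    )
    dataset = build_dataset(
        proteins, sites, flank=flank, negative_subsample=n_negative, seed=seed
    )
    if dataset.n_positive > n_positive:
        rng = np.random.default_rng(seed + 1)
        pos_idx = np.flatnonzero(dataset.labels == 1)
        neg_idx = np.flatnonzero(dataset.labels == 0)
        keep_pos = rng.choice(pos_idx, size=n_positive, replace=False)
        dataset = dataset.subset(np.sort(np.concatenate([keep_pos, neg_idx])))
    return dataset
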