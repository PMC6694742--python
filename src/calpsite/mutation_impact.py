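"""Missense-variant effects on predicted cleavage and positional enrichment testing.

A substitution at residue ``pos`` can only change the score of bonds whose
window covers ``pos``: bonds ``b`` with ``b - flank + 1 <= pos <= b + flank``.
The affected bonds are scored on the original and the mutated sequence and
the two predicted site sets compared:

* ``no_change`` — the site sets are identical (including both empty);
* ``gain``      — every old site is kept and at least one new one appears;
* ``loss``      — sites existed before and none survive;
* ``change``    — anything else (sites shifted, or partially lost, or mixed
  gain and loss).  This residual reading makes the four categories a
  partition of all (before, after) set pairs.

The enrichment test asks whether observed variants sit closer to annotated
cleavage bonds than chance would place them: the observed statistic is the
fraction of variants within ±flank of any annotated bond of their protein,
and the null resamples each variant's position uniformly over its own
protein, preserving per-protein variant counts (and thereby protein length
and mutation burden).  The empirical p-value uses the +1 correction, so it
can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .nn import TrainedModel, predict_scores
from .sequence_io import CleavageSite, MissenseVariant, Protein

CATEGORIES = ("gain", "loss", "change", "no_change")


def apply_missense(protein: Protein, variant: MissenseVariant) -> Protein:
    """Return the protein with the variant's substitution applied (same id, same length)."""
    if variant.protein_id != protein.id:
        raise ValueError(f"variant protein {variant.protein_id!r} is not {protein.id!r}")
    if variant.position > len(protein):
        raise ValueError(f"variant position {variant.position} beyond protein length")
    i = variant.position - 1
    if protein.sequence[i] != variant.ref:
        raise ValueError(
            f"variant {protein.id}:{variant.position}{variant.ref}>{variant.alt}: "
            f"sequence has {protein.sequence[i]!r} at that position"
        )
    seq = protein.sequence[:i] + variant.alt + protein.sequence[i + 1 :]
    return Protein(protein.id, seq)


def affected_bonds(position: int, protein_length: int, flank: int = 15) -> set[int]:
    """Bonds whose window covers the residue at ``position``.

    These are bonds ``b`` with ``b - flank + 1 <= position <= b + flank``,
    intersected with the valid bond range ``[1, L-1]``.
    """
    lo = max(1, position - flank)
    hi = min(protein_length - 1, position + flank - 1)
    return set(range(lo, hi + 1))


@dataclass(frozen=True)
class ImpactCall:
    """One variant's verdict with the before/after predicted site sets."""

    variant: MissenseVariant
    category: str
    sites_before: frozenset[int]
    sites_after: frozenset[int]
    threshold: float


def categorize_site_sets(before: set[int], after: set[int]) -> str:
    """The gain/loss/change/no-change verdict from before/after predicted site sets."""
    before, after = set(before), set(after)
    if before == after:
        return "no_change"
    if before < after:
        return "gain"
    if not after:
        return "loss"
    return "change"


def classify_impact(
    model: TrainedModel,
    protein: Protein,
    variant: MissenseVariant,
    threshold: float = 0.5,
) -> ImpactCall:
    """Score the variant's affected bonds before and after mutation and categorize.

    Only bonds whose window covers the mutated residue are scored (the
    substitution cannot move any other window's score); a bond is a predicted
    site when its cleavage score reaches ``threshold``.
    """
    flank = model.flank
    bonds = sorted(affected_bonds(variant.position, len(protein), flank))
    mutated = apply_missense(protein, variant)
    if bonds:
        positions = {protein.id: bonds}
        before_scores = predict_scores(model, [protein], positions)
        after_scores = predict_scores(model, [mutated], positions)
        before = {r.bond for r in before_scores if r.score >= threshold}
        after = {r.bond for r in after_scores if r.score >= threshold}
    else:
        before, after = set(), set()
    return ImpactCall(
        variant=variant,
        category=categorize_site_sets(before, after),
        sites_before=frozenset(before),
        sites_after=frozenset(after),
        threshold=threshold,
    )


def cohort_summary(
    calls: Sequence[ImpactCall],
) -> pd.DataFrame:
    """Per-category variant, affected-site, and distinct-protein counts.

    The site count aggregates the symmetric difference of each call's
    before/after sets.  A protein with calls in several categories counts once
    in each of those categories.
    """
    rows = []
    for cat in CATEGORIES:
        in_cat = [c for c in calls if c.category == cat]
        n_sites = sum(len(c.sites_before ^ c.sites_after) for c in in_cat)
        rows.append(
            {
                "category": cat,
                "n_variants": len(in_cat),
                "n_sites_affected": n_sites,
                "n_proteins": len({c.variant.protein_id for c in in_cat}),
            }
        )
    return pd.DataFrame(rows)


def impact_table(calls: Sequence[ImpactCall]) -> pd.DataFrame:
    """One row per variant call, ready for TSV export."""
    return pd.DataFrame(
        {
            "protein_id": [c.variant.protein_id for c in calls],
            "pos": [c.variant.position for c in calls],
            "ref": [c.variant.ref for c in calls],
            "alt": [c.variant.alt for c in calls],
            "category": [c.category for c in calls],
            "sites_before": [
                ",".join(str(b) for b in sorted(c.sites_before)) for c in calls
            ],
            "sites_after": [
                ",".join(str(b) for b in sorted(c.sites_after)) for c in calls
            ],
        }
    )


@dataclass
class EnrichmentResult:
    """Observed near-site variant fraction against its positional-resampling null."""

    observed: float
    null_mean: float
    null_sd: float
    ratio: float
    p_value: float
    n_iterations: int
    seed: int

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([self.__dict__]).to_csv(path, sep="\t", index=False)


def bootstrap_site_enrichment(
    variants: Sequence[MissenseVariant],
    sites: Sequence[CleavageSite],
    proteins: Sequence[Protein],
    flank: int = 15,
    n_iterations: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Test whether variants cluster within ±flank residues of annotated cleavage bonds.

    observed = fraction of variants whose position lies in some annotated
    bond's window in their protein.  Null iterations redraw every variant's
    position uniformly (with replacement) over its own protein's residues.
    p = (1 + #{null >= observed}) / (n_iterations + 1).
    """
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    if not variants:
        raise ValueError("no variants to test")
    by_id = {p.id: p for p in proteins}
    site_bonds: dict[str, list[int]] = {}
    for s in sites:
        site_bonds.setdefault(s.protein_id, []).append(s.bond)

    # per protein: boolean near-site mask over residue positions 1..L
    near_mask: dict[str, np.ndarray] = {}
    for pid, prot in by_id.items():
        mask = np.zeros(len(prot) + 1, dtype=bool)  # index 0 unused
        for bond in site_bonds.get(pid, []):
            lo = max(1, bond - flank + 1)
            hi = min(len(prot), bond + flank)
            mask[lo : hi + 1] = True
        near_mask[pid] = mask

    per_protein: dict[str, list[int]] = {}
    for v in variants:
        if v.protein_id not in by_id:
            raise ValueError(f"variant protein {v.protein_id!r} has no sequence")
        per_protein.setdefault(v.protein_id, []).append(v.position)

    n_var = len(variants)
    observed_hits = 0
    null_hits = np.zeros(n_iterations, dtype=np.int64)
    rng = np.random.default_rng(seed)
    for pid, positions in per_protein.items():
        mask = near_mask[pid]
        L = len(by_id[pid])
        pos = np.asarray(positions)
        observed_hits += int(mask[pos].sum())
        draws = rng.integers(1, L + 1, size=(n_iterations, len(positions)))
        null_hits += mask[draws].sum(axis=1)

    observed = observed_hits / n_var
    null_frac = null_hits / n_var
    null_mean = float(null_frac.mean())
    null_sd = float(null_frac.std(ddof=1))
    p = float((1 + int(np.sum(null_frac >= observed))) / (n_iterations + 1))
    return EnrichmentResult(
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        ratio=float(observed / null_mean) if null_mean > 0 else float("inf"),
        p_value=p,
        n_iterations=n_iterations,
        seed=seed,
    )
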