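"""Cross-cohort variant reconciliation and dataset merging.

Variants are matched by rsID alone (the HapMap3-intersection convention);
position disagreements between cohorts are logged, not fatal.  Strand-
ambiguous (palindromic) SNPs — A/T, T/A, C/G, G/C — can never be oriented
reliably from genotype files and are always dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .datasets import _COMPLEMENT, MISSING, GenotypeDataset, VariantRecord

logger = logging.getLogger(__name__)


class AlignAction(str, Enum):
    KEEP = "keep"
    SWAP = "swap"                      # allele1/2 exchanged; dosage <- 2 - dosage
    STRAND_FLIP = "strand_flip"        # complement both alleles, dosage unchanged
    SWAP_AND_FLIP = "swap_and_flip"
    DROP_AMBIGUOUS = "drop_ambiguous"
    DROP_MISMATCH = "drop_mismatch"

    @property
    def drops(self) -> bool:
        return self in (AlignAction.DROP_AMBIGUOUS, AlignAction.DROP_MISMATCH)

    @property
    def swaps(self) -> bool:
        return self in (AlignAction.SWAP, AlignAction.SWAP_AND_FLIP)

    @property
    def inverse(self) -> "AlignAction":
        # every action is its own inverse (aligning the other way)
        return self


@dataclass
class AlleleAlignment:
    """Per shared variant, how cohort b's alleles map onto cohort a's."""

    actions: dict[str, AlignAction]

    def kept_ids(self) -> list[str]:
        return [vid for vid, a in self.actions.items() if not a.drops]


def _flip(allele: str) -> str:
    return _COMPLEMENT.get(allele, allele)


def classify_pair(a: VariantRecord, b: VariantRecord) -> AlignAction:
    """Alignment action taking b's (allele1, allele2) onto a's."""
    if a.is_ambiguous or b.is_ambiguous:
        return AlignAction.DROP_AMBIGUOUS
    pa = (a.allele1, a.allele2)
    if (b.allele1, b.allele2) == pa:
        return AlignAction.KEEP
    if (b.allele2, b.allele1) == pa:
        return AlignAction.SWAP
    if (_flip(b.allele1), _flip(b.allele2)) == pa:
        return AlignAction.STRAND_FLIP
    if (_flip(b.allele2), _flip(b.allele1)) == pa:
        return AlignAction.SWAP_AND_FLIP
    return AlignAction.DROP_MISMATCH


def align_alleles(
    a: list[VariantRecord], b: list[VariantRecord]
) -> AlleleAlignment:
    """Classify every variant id shared between panels ``a`` and ``b``.

    Duplicated rsIDs within a panel are resolved first-kept (logged).
    """
    a_by_id = _dedup(a, "a")
    b_by_id = _dedup(b, "b")
    actions: dict[str, AlignAction] = {}
    for vid in a_by_id:
        if vid not in b_by_id:
            continue
        va, vb = a_by_id[vid], b_by_id[vid]
        action = classify_pair(va, vb)
        if va.position != vb.position or va.chromosome != vb.chromosome:
            logger.warning("%s: position differs between cohorts (%s:%d vs %s:%d)",
                           vid, va.chromosome, va.position, vb.chromosome, vb.position)
        if action == AlignAction.DROP_MISMATCH:
            logger.warning("%s: incompatible alleles %s/%s vs %s/%s — dropped",
                           vid, va.allele1, va.allele2, vb.allele1, vb.allele2)
        actions[vid] = action
    return AlleleAlignment(actions=actions)


def _dedup(records: list[VariantRecord], label: str) -> dict[str, VariantRecord]:
    out: dict[str, VariantRecord] = {}
    dropped = 0
    for r in records:
        if r.id in out:
            dropped += 1
            continue
        out[r.id] = r
    if dropped:
        logger.warning("panel %s: %d duplicated rsIDs dropped (first kept)", label, dropped)
    return out


def merge_datasets(
    a: GenotypeDataset, b: GenotypeDataset, alignment: AlleleAlignment
) -> GenotypeDataset:
    """Merge two cohorts on the variants surviving ``alignment``.

    Output variant metadata (and dosage orientation) follow cohort ``a``;
    sample order is a's samples then b's.  Sample id sets must be disjoint —
    the downstream models require independent cohorts.
    """
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValueError(f"overlapping sample ids between cohorts: {sorted(overlap)[:5]}")

    kept = [vid for vid in alignment.kept_ids()]
    a_index = {v.id: i for i, v in enumerate(a.variants)}
    b_index = {v.id: i for i, v in enumerate(b.variants)}
    # preserve cohort a's variant order
    kept = [v.id for v in a.variants if v.id in set(kept) and v.id in b_index]

    rows_a = np.array([a_index[v] for v in kept], dtype=int)
    rows_b = np.array([b_index[v] for v in kept], dtype=int)
    calls_a = a.calls[rows_a, :]
    calls_b = b.calls[rows_b, :].copy()
    for k, vid in enumerate(kept):
        if alignment.actions[vid].swaps:
            row = calls_b[k]
            nonmiss = row != MISSING
            row[nonmiss] = 2 - row[nonmiss]

    samples = pd.concat([a.samples, b.samples], ignore_index=True)
    return GenotypeDataset(
        variants=[a.variants[i] for i in rows_a],
        samples=samples,
        calls=np.concatenate([calls_a, calls_b], axis=1),
    )
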