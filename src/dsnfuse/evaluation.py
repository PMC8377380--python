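"""Partition and network quality statistics.

Covers normalized mutual information against the ATC label vector, the
ATC / superclass overlap rates of a drug-pair set, the Rogers--Tanimoto
pair-counting agreement between two partitions, and the sliding-bin AOR
curve along a similarity-ranked pair list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from dsnfuse.clustering import ClusterAssignment
from dsnfuse.core_io import DrugRecord

logger = logging.getLogger("dsnfuse")


@dataclass
class RankedPairList:
    """Drug pairs ordered by descending similarity score.

    Pairs are canonical (drug_a < drug_b) and unique; ties keep the
    canonical lexicographic pair order.
    """

    pairs: list[tuple[str, str, float]]

    def __post_init__(self):
        seen = set()
        prev = np.inf
        for a, b, s in self.pairs:
            if not a < b:
                raise ValueError(f"pair ({a}, {b}) not in canonical order")
            if (a, b) in seen:
                raise ValueError(f"duplicate pair ({a}, {b})")
            seen.add((a, b))
            if s > prev + 1e-12:
                raise ValueError("scores not descending")
            prev = s

    def __len__(self):
        return len(self.pairs)


def nmi(labels_x: Sequence, labels_y: Sequence) -> float:
    """Normalized mutual information MI(X, Y)/sqrt(H(X) H(Y)), log base 2.

    Returns 0 when either marginal entropy is 0 (single-label vector),
    where the quotient is undefined.
    """
    if len(labels_x) != len(labels_y):
        raise ValueError("label vectors differ in length")
    x = np.asarray(labels_x)
    y = np.asarray(labels_y)
    n = len(x)
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((len(xs), len(ys)))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    hx = -np.sum(px[px > 0] * np.log2(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log2(py[py > 0]))
    if hx <= 0 or hy <= 0:
        return 0.0
    nz = joint > 0
    mi = np.sum(joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz]))
    return float(max(0.0, mi / np.sqrt(hx * hy)))


def _registry_index(registry: Iterable[DrugRecord]) -> dict[str, DrugRecord]:
    return {r.drug_id: r for r in registry}


def aor(pairs: Iterable[tuple[str, str]], registry: Iterable[DrugRecord]) -> float:
    """ATC overlap rate: fraction of pairs whose first-level ATC code sets
    intersect.  Pairs involving a drug without ATC annotation are excluded
    (and counted in the log) rather than scored as non-overlap."""
    idx = _registry_index(registry)
    hits = total = skipped = 0
    for a, b in pairs:
        fa = idx[a].atc_first_levels
        fb = idx[b].atc_first_levels
        if not fa or not fb:
            skipped += 1
            continue
        total += 1
        if fa & fb:
            hits += 1
    if skipped:
        logger.info("AOR: %d pairs excluded for missing ATC annotation", skipped)
    if total == 0:
        raise ValueError("no evaluable pairs (empty set or all missing ATC)")
    return hits / total


def sor(pairs: Iterable[tuple[str, str]], registry: Iterable[DrugRecord]) -> float:
    """Superclass overlap rate: fraction of pairs with identical superclass
    labels, excluding pairs with missing labels."""
    idx = _registry_index(registry)
    hits = total = skipped = 0
    for a, b in pairs:
        sa = idx[a].superclass
        sb = idx[b].superclass
        if sa is None or sb is None:
            skipped += 1
            continue
        total += 1
        if sa == sb:
            hits += 1
    if skipped:
        logger.info("SOR: %d pairs excluded for missing superclass", skipped)
    if total == 0:
        raise ValueError("no evaluable pairs (empty set or all missing superclass)")
    return hits / total


def rogers_tanimoto(p1: ClusterAssignment, p2: ClusterAssignment) -> float:
    """Rogers--Tanimoto agreement between two partitions of the same drugs.

    Over all unordered drug pairs: (n11 + n00) / (n11 + n00 + 2 (n10 + n01))
    where n11/n00 count pairs co-clustered/separated in both partitions and
    n10/n01 count disagreements.  Invariant to cluster relabeling.
    """
    if set(p1.labels) != set(p2.labels):
        raise ValueError("partitions cover different drug sets")
    drugs = sorted(p1.labels)
    v1 = p1.vector(drugs)
    v2 = p2.vector(drugs)
    same1 = v1[:, None] == v1[None, :]
    same2 = v2[:, None] == v2[None, :]
    iu = np.triu_indices(len(drugs), k=1)
    s1, s2 = same1[iu], same2[iu]
    n11 = int(np.sum(s1 & s2))
    n00 = int(np.sum(~s1 & ~s2))
    n10 = int(np.sum(s1 & ~s2))
    n01 = int(np.sum(~s1 & s2))
    return (n11 + n00) / (n11 + n00 + 2 * (n10 + n01))


def atc_label_vector(
    drugs: Sequence[str],
    registry: Iterable[DrugRecord],
    reduce: str = "first",
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Reduce each drug's ATC code set to a single first-level label.

    ``reduce="first"`` takes the alphabetically first first-level code;
    ``"random-seeded"`` draws one uniformly under the given seed.  Drugs
    without ATC codes are omitted; the retained drug list is returned
    alongside the labels.
    """
    idx = _registry_index(registry)
    rng = np.random.default_rng(seed)
    kept, labels = [], []
    for d in drugs:
        levels = sorted(idx[d].atc_first_levels)
        if not levels:
            continue
        kept.append(d)
        if reduce == "first":
            labels.append(levels[0])
        elif reduce == "random-seeded":
            labels.append(levels[rng.integers(len(levels))])
        else:
            raise ValueError(f"unknown ATC reduction {reduce!r}")
    return kept, labels


def aor_curve(
    ranked: RankedPairList,
    registry: Iterable[DrugRecord],
    bin_size: int = 3000,
    step: int = 100,
    n_bins: int | None = None,
) -> list[tuple[int, float]]:
    """AOR inside a bin slid down the ranked pair list.

    Returns (start rank, AOR) per window; the published defaults are a
    3000-pair bin with step 100, both configurable for small runs.
    """
    total = len(ranked)
    if n_bins is None:
        n_bins = (total - bin_size) // step + 1
    needed = bin_size + (n_bins - 1) * step
    if n_bins < 1 or total < needed:
        raise ValueError(
            f"ranked list of {total} pairs too short: need >= {needed} "
            f"for {n_bins} bins of {bin_size} at step {step}"
        )
    reg = list(registry)
    curve = []
    for b in range(n_bins):
        start = b * step
        window = [(a, c) for a, c, _ in ranked.pairs[start : start + bin_size]]
        curve.append((start, aor(window, reg)))
    return curve
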