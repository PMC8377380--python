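"""Synthetic drug universes with planted cluster structure.

The generator plants a drug partition and expresses it, with separately
tunable signal-to-noise, in three complementary property views:

* a side-effect view — each cluster has a disjoint signature of
  side-effect terms; per-drug noise drops signature terms and adds random
  vocabulary terms;
* a chemical view — identical mechanics over an atom-pair-like token
  namespace;
* a target view — each cluster has an anchor protein sequence and every
  drug carries a point-mutated copy, so normalized Smith--Waterman
  similarity is high within clusters and near background between them.

A view may be *uninformative* for some clusters: those clusters draw
their features from one shared background signature (or background
anchor), so the view cannot separate them.  ATC codes follow each
cluster's dominant first-level code, with a label-noise rate that flips a
drug's code to a random other code — flipped drugs are the ground truth
for the unexpected-drug repositioning route.  Everything is deterministic
given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dsnfuse.clustering import ClusterAssignment
from dsnfuse.core_io import (
    DrugRecord,
    FeatureProfile,
    SequenceDB,
    TargetMap,
    write_cluster_assignment,
    write_drug_registry,
    write_feature_profiles,
    write_target_map,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ATC_LETTERS = sorted("ABCDGHJLMNPRSV")


@dataclass
class UniverseSpec:
    """Parameters of a synthetic drug universe."""

    n_drugs: int = 120
    n_clusters: int = 6
    # side-effect view
    se_vocab_size: int = 400
    se_signature_size: int = 25
    se_noise: float = 0.0
    se_informative: tuple[int, ...] | None = None  # None = all clusters
    # chemical (atom-pair) view
    ap_vocab_size: int = 400
    ap_signature_size: int = 25
    ap_noise: float = 0.0
    ap_informative: tuple[int, ...] | None = None
    # target view
    seq_length: int = 120
    mutation_rate: float = 0.0
    target_informative: tuple[int, ...] | None = None
    # labels
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters > self.n_drugs // 4:
            raise ValueError("need at least 4 drugs per cluster")
        for rate in (self.se_noise, self.ap_noise, self.mutation_rate, self.label_noise):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("noise rates must lie in [0, 1]")
        for vocab, sig in (
            (self.se_vocab_size, self.se_signature_size),
            (self.ap_vocab_size, self.ap_signature_size),
        ):
            if (self.n_clusters + 1) * sig > vocab:
                raise ValueError(
                    "vocabulary too small for disjoint cluster signatures"
                )
        if self.n_clusters > len(_ATC_LETTERS):
            raise ValueError("more clusters than first-level ATC codes")
        covered = set()
        for info in (self.se_informative, self.ap_informative, self.target_informative):
            covered |= set(info) if info is not None else set(range(1, self.n_clusters + 1))
        if covered != set(range(1, self.n_clusters + 1)):
            raise ValueError("every cluster must be informative in at least one view")

    def informative_for(self, view: str) -> set[int]:
        info = {
            "side_effect": self.se_informative,
            "atom_pair": self.ap_informative,
            "target": self.target_informative,
        }[view]
        return set(info) if info is not None else set(range(1, self.n_clusters + 1))


@dataclass
class SyntheticUniverse:
    """Everything :func:`simulate_universe` produces for one seed."""

    spec: UniverseSpec
    registry: list[DrugRecord]
    side_effects: list[FeatureProfile]
    atom_pairs: list[FeatureProfile]
    target_maps: list[TargetMap]
    sequences: SequenceDB
    planted: ClusterAssignment
    flipped: dict[str, str] = field(default_factory=dict)  # drug -> true code

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_drug_registry(self.registry, outdir / "drugs.tsv")
        write_feature_profiles(self.side_effects, outdir / "side_effects.tsv")
        write_feature_profiles(self.atom_pairs, outdir / "atom_pairs.tsv")
        write_target_map(self.target_maps, outdir / "targets.tsv")
        self.sequences.to_fasta(outdir / "proteins.fasta")
        write_cluster_assignment(self.planted.labels, outdir / "planted_clusters.tsv")


def _token_signatures(
    rng: np.random.Generator, prefix: str, vocab_size: int, sig_size: int, n_clusters: int
) -> tuple[list[list[str]], list[str], list[str]]:
    """Disjoint per-cluster signatures plus a shared background signature."""
    vocab = [f"{prefix}{i:05d}" for i in range(vocab_size)]
    perm = rng.permutation(vocab_size)
    signatures = [
        [vocab[perm[c * sig_size + i]] for i in range(sig_size)]
        for c in range(n_clusters)
    ]
    background = [
        vocab[perm[n_clusters * sig_size + i]] for i in range(sig_size)
    ]
    return signatures, background, vocab


def _noisy_profile(
    rng: np.random.Generator, signature: list[str], vocab: list[str], noise: float
) -> frozenset[str]:
    kept = [t for t in signature if rng.random() >= noise]
    n_extra = rng.binomial(len(signature), noise)
    extra = [vocab[i] for i in rng.integers(0, len(vocab), size=n_extra)]
    return frozenset(kept) | frozenset(extra)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(ch, "")
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(ch)
    return "".join(out)


def simulate_universe(spec: UniverseSpec) -> SyntheticUniverse:
    """Generate one synthetic universe according to the spec."""
    rng = np.random.default_rng(spec.seed)
    k = spec.n_clusters
    drugs = [f"D{i:04d}" for i in range(spec.n_drugs)]
    planted_vec = [(i % k) + 1 for i in range(spec.n_drugs)]
    planted = ClusterAssignment({d: c for d, c in zip(drugs, planted_vec)}, k)

    se_sigs, se_bg, se_vocab = _token_signatures(
        rng, "se", spec.se_vocab_size, spec.se_signature_size, k
    )
    ap_sigs, ap_bg, ap_vocab = _token_signatures(
        rng, "ap", spec.ap_vocab_size, spec.ap_signature_size, k
    )
    anchors = [
        "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=spec.seq_length))
        for _ in range(k + 1)  # one per cluster plus the background anchor
    ]

    se_info = spec.informative_for("side_effect")
    ap_info = spec.informative_for("atom_pair")
    tg_info = spec.informative_for("target")

    side_effects, atom_pairs, target_maps = [], [], []
    sequences = SequenceDB()
    registry, flipped = [], {}
    for d, c in zip(drugs, planted_vec):
        se_sig = se_sigs[c - 1] if c in se_info else se_bg
        ap_sig = ap_sigs[c - 1] if c in ap_info else ap_bg
        side_effects.append(
            FeatureProfile(d, _noisy_profile(rng, se_sig, se_vocab, spec.se_noise), "side_effect")
        )
        atom_pairs.append(
            FeatureProfile(d, _noisy_profile(rng, ap_sig, ap_vocab, spec.ap_noise), "atom_pair")
        )
        anchor = anchors[c - 1] if c in tg_info else anchors[k]
        pid = f"P_{d}"
        sequences[pid] = _mutate(rng, anchor, spec.mutation_rate)
        target_maps.append(TargetMap(d, frozenset([pid])))

        true_code = _ATC_LETTERS[c - 1]
        code = true_code
        if rng.random() < spec.label_noise:
            others = [x for x in _ATC_LETTERS if x != true_code]
            code = others[rng.integers(len(others))]
            flipped[d] = true_code
        registry.append(
            DrugRecord(
                drug_id=d,
                name=f"drug-{d}",
                atc_codes=frozenset([f"{code}01"]),
                superclass=f"class_{true_code}",
            )
        )
    return SyntheticUniverse(
        spec=spec,
        registry=registry,
        side_effects=side_effects,
        atom_pairs=atom_pairs,
        target_maps=target_maps,
        sequences=sequences,
        planted=planted,
        flipped=flipped,
    )


def complementary_benchmark(seed: int = 0) -> UniverseSpec:
    """The canned three-view complementarity benchmark.

    120 drugs in 6 planted clusters; each view can separate only part of
    the cluster structure — side effects clusters {1, 2, 3}, chemistry
    {3, 4, 5}, targets {5, 6, 1} — but the union covers all six, so only
    an integrator that pools complementary signal can recover the full
    partition.  Noise is moderate in every view.
    """
    return UniverseSpec(
        n_drugs=120,
        n_clusters=6,
        se_noise=0.2,
        se_informative=(1, 2, 3),
        ap_noise=0.2,
        ap_informative=(3, 4, 5),
        mutation_rate=0.1,
        target_informative=(5, 6, 1),
        label_noise=0.0,
        seed=seed,
    )
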