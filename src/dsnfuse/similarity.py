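"""Single-property drug similarity networks.

Three views are supported: clinical (Tanimoto over filtered side-effect
profiles), chemical (Tanimoto over atom-pair descriptor sets) and
pharmacological (normalized Smith--Waterman similarity over drug target
protein sets).  Every builder returns a unit-scale
:class:`~dsnfuse.core_io.SimilarityMatrix`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import AbstractSet, Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from dsnfuse.core_io import (
    FeatureProfile,
    SequenceDB,
    SimilarityMatrix,
    TargetMap,
)

logger = logging.getLogger("dsnfuse")


@dataclass(frozen=True)
class AlignmentScoring:
    """Parameters of the Smith--Waterman kernel.

    With ``matrix`` set, residue pairs are scored by the named substitution
    matrix (default BLOSUM62); otherwise by ``match``/``mismatch``.  A gap
    of length L costs ``gap_open + (L - 1) * gap_extend``.  Defaults follow
    the common EMBOSS-water protein settings.
    """

    matrix: str | None = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    match: float = 1.0
    mismatch: float = -1.0

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner(mode="local")
        if self.matrix is not None:
            aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    @property
    def alphabet(self) -> frozenset[str]:
        if self.matrix is not None:
            return frozenset(substitution_matrices.load(self.matrix).alphabet)
        return frozenset("ACDEFGHIKLMNPQRSTVWYX")


def filter_side_effect_terms(
    profiles: Sequence[FeatureProfile],
    min_count: int = 1,
    min_frequency: float = 0.001,
) -> list[FeatureProfile]:
    """Drop unreliable side-effect terms from every profile.

    A term is removed when it occurs for at most ``min_count`` drugs in the
    whole corpus, or when its attached report frequency is below
    ``min_frequency`` (default 0.1%).  The frequency rule only fires for
    drug--term pairs that actually carry frequency data.  Drugs left with
    empty profiles are retained and flagged in the log.
    """
    if any(p.kind != "side_effect" for p in profiles):
        raise ValueError("filter applies to side_effect profiles only")
    counts: dict[str, int] = {}
    for p in profiles:
        for t in p.features:
            counts[t] = counts.get(t, 0) + 1
    rare = {t for t, c in counts.items() if c <= min_count}
    out = []
    for p in profiles:
        kept = {
            t
            for t in p.features
            if t not in rare
            and not (t in p.frequencies and p.frequencies[t] < min_frequency)
        }
        if not kept and p.features:
            logger.warning("drug %s left with an empty side-effect profile", p.drug_id)
        out.append(
            FeatureProfile(
                p.drug_id,
                frozenset(kept),
                p.kind,
                {t: f for t, f in p.frequencies.items() if t in kept},
            )
        )
    return out


def tanimoto(a: AbstractSet, b: AbstractSet) -> float:
    """Tanimoto (Jaccard) coefficient |a ∩ b| / |a ∪ b|.

    Two empty sets score 0: absence of evidence must not assert maximal
    similarity.
    """
    shared = len(a & b)
    denom = len(a) + len(b) - shared
    return shared / denom if denom else 0.0


def build_profile_dsn(profiles: Sequence[FeatureProfile]) -> SimilarityMatrix:
    """Pairwise Tanimoto similarity network over feature profiles."""
    drugs = [p.drug_id for p in profiles]
    if len(set(drugs)) != len(drugs):
        raise ValueError("duplicate drug_id among profiles")
    if len(drugs) < 2:
        raise ValueError("need at least 2 drugs")
    n = len(drugs)
    vals = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        vals[i, j] = vals[j, i] = tanimoto(profiles[i].features, profiles[j].features)
    return SimilarityMatrix(drugs, vals, "unit")


def smith_waterman(seq1: str, seq2: str, scoring: AlignmentScoring) -> float:
    """Optimal local-alignment score under affine gaps."""
    alphabet = scoring.alphabet
    for seq in (seq1, seq2):
        if not seq:
            raise ValueError("empty sequence")
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(f"residues outside alphabet: {sorted(bad)}")
    return float(scoring.make_aligner().score(seq1, seq2))


def target_similarity(
    pa: AbstractSet[str],
    pb: AbstractSet[str],
    db: SequenceDB,
    scoring: AlignmentScoring,
    _self_scores: dict[str, float] | None = None,
) -> float:
    """Normalized Smith--Waterman similarity between two target sets.

    Every cross pair (p, q) contributes SW(p, q) / sqrt(SW(p, p) SW(q, q))
    — the geometric-mean normalization, so that a protein aligned with
    itself scores exactly 1 — and the contributions are averaged over the
    |Pa| x |Pb| pairs.  The result is clipped to [0, 1].
    """
    if not pa or not pb:
        raise ValueError("target sets must be non-empty")
    for pid in set(pa) | set(pb):
        if pid not in db:
            raise KeyError(f"protein {pid!r} not found in sequence database")
    cache = _self_scores if _self_scores is not None else {}

    def self_score(pid: str) -> float:
        if pid not in cache:
            cache[pid] = smith_waterman(db[pid], db[pid], scoring)
        return cache[pid]

    total = 0.0
    for p in pa:
        for q in pb:
            denom = np.sqrt(self_score(p) * self_score(q))
            cross = smith_waterman(db[p], db[q], scoring)
            total += cross / denom if denom > 0 else 0.0
    return float(np.clip(total / (len(pa) * len(pb)), 0.0, 1.0))


def build_target_dsn(
    target_maps: Sequence[TargetMap],
    db: SequenceDB,
    scoring: AlignmentScoring | None = None,
) -> SimilarityMatrix:
    """Pairwise normalized-SW similarity network over drug target sets.

    Self-alignment scores are computed once per protein and shared across
    all pairs.  The diagonal is forced to 1.
    """
    scoring = scoring or AlignmentScoring()
    drugs = [t.drug_id for t in target_maps]
    if len(set(drugs)) != len(drugs):
        raise ValueError("duplicate drug_id among target maps")
    for t in target_maps:
        if not t.protein_ids:
            raise ValueError(f"drug {t.drug_id} has no targets")
    n = len(drugs)
    self_scores: dict[str, float] = {}
    vals = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        vals[i, j] = vals[j, i] = target_similarity(
            target_maps[i].protein_ids,
            target_maps[j].protein_ids,
            db,
            scoring,
            _self_scores=self_scores,
        )
    return SimilarityMatrix(drugs, vals, "unit")


def atom_pair_features(smiles: str) -> frozenset[str]:
    """Atom-pair descriptor tokens of a structure given as SMILES.

    Each token encodes a typed heavy-atom pair and its topological
    distance, as produced by the RDKit atom-pair fingerprint; tokens are
    prefixed ``ap:`` to keep the chemical namespace disjoint from
    side-effect terms.  Requires the optional rdkit dependency.
    """
    from rdkit import Chem
    from rdkit.Chem import rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    fp = rdMolDescriptors.GetAtomPairFingerprint(mol)
    return frozenset(f"ap:{code}" for code in fp.GetNonzeroElements())


def profiles_from_smiles(pairs: Iterable[tuple[str, str]]) -> list[FeatureProfile]:
    """Build atom-pair profiles from (drug_id, smiles) pairs."""
    return [
        FeatureProfile(drug_id, atom_pair_features(smi), "atom_pair")
        for drug_id, smi in pairs
    ]
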