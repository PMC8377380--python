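"""Domain data model and plain-text readers/writers.

All on-disk formats are diff-able text: tab-separated tables for the drug
registry, sparse feature pairs, drug--target maps and similarity matrices;
FASTA for protein sequences; JSON for run configuration.  Matrices are
stored dense because the networks involved have only hundreds of drugs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("dsnfuse")

#: Valid first-level letters of the Anatomical Therapeutic Chemical system.
ATC_FIRST_LEVELS = frozenset("ABCDGHJLMNPRSV")

FEATURE_KINDS = ("side_effect", "atom_pair")


def atc_first_level(code: str) -> str:
    """Reduce a full ATC code (e.g. ``N02BA01``) to its first-level letter."""
    if not code or code[0].upper() not in ATC_FIRST_LEVELS:
        raise ValueError(f"malformed ATC code: {code!r}")
    return code[0].upper()


@dataclass(frozen=True)
class DrugRecord:
    """A drug's identity and the label vocabularies used downstream.

    ``atc_codes`` may be empty; such drugs stay in every network but are
    excluded (with logging) from ATC-based evaluation metrics.
    """

    drug_id: str
    name: str = ""
    atc_codes: frozenset[str] = frozenset()
    superclass: str | None = None

    @property
    def atc_first_levels(self) -> frozenset[str]:
        return frozenset(atc_first_level(c) for c in self.atc_codes)


@dataclass(frozen=True)
class FeatureProfile:
    """A drug's set of discrete feature tokens (side-effect terms or
    atom-pair descriptors).  Frequencies, when known, are kept per token for
    the side-effect filtering step."""

    drug_id: str
    features: frozenset[str]
    kind: str
    frequencies: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}")


@dataclass(frozen=True)
class TargetMap:
    """Per-drug protein-target set."""

    drug_id: str
    protein_ids: frozenset[str]


class SequenceDB(dict):
    """protein_id -> uppercase single-letter amino-acid sequence."""

    def __setitem__(self, key: str, seq: str):
        if not seq:
            raise ValueError(f"empty sequence for protein {key!r}")
        super().__setitem__(key, seq.upper())

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceDB":
        db = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            db[rec.id] = str(rec.seq)
        return db

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for pid, seq in self.items():
                fh.write(f">{pid}\n{seq}\n")


@dataclass
class SimilarityMatrix:
    """Symmetric drug-by-drug score matrix with an ordered drug index.

    ``scale`` is ``"unit"`` for raw similarity networks (entries in [0, 1],
    unit diagonal) or ``"affinity"`` for fusion output, where rows carry
    diffusion mass and are only guaranteed symmetric and non-negative.
    """

    drugs: list[str]
    values: np.ndarray
    scale: str = "unit"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.drugs)
        if len(set(self.drugs)) != n:
            raise ValueError("duplicate drug_id in matrix index")
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9, rtol=0):
            raise ValueError("matrix is not symmetric")
        if np.any(self.values < 0):
            raise ValueError("matrix has negative entries")
        if self.scale == "unit":
            if np.any(self.values > 1 + 1e-9):
                raise ValueError("unit-scale matrix has entries > 1")
            if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
                raise ValueError("unit-scale matrix diagonal is not 1")
        elif self.scale != "affinity":
            raise ValueError(f"unknown scale {self.scale!r}")

    def index_of(self, drug_id: str) -> int:
        return self.drugs.index(drug_id)

    def subset(self, drug_ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.drugs.index(d) for d in drug_ids]
        return SimilarityMatrix(list(drug_ids), self.values[np.ix_(idx, idx)], self.scale)


@dataclass
class RunConfig:
    """Run-wide parameters with the framework's published defaults."""

    eta: float = 0.5
    K: int = 20
    T: int = 20
    k_min: int = 2
    k_max: int = 40
    margin: float = 0.10
    bin_size: int = 3000
    step: int = 100
    alpha: float = 0.05
    L: int = 10
    seed: int = 0
    min_count: int = 1
    min_frequency: float = 0.001
    atc_reduce: str = "first"
    margin_mode: str = "relative"
    significance_column: str = "p"
    top_frac: float = 0.05

    def __post_init__(self):
        if self.eta <= 0 or self.K < 1 or self.T < 1:
            raise ValueError("fusion parameters must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({f.name: getattr(self, f.name) for f in fields(self)}, indent=2),
            encoding="utf-8",
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_drug_registry(path: str | Path) -> list[DrugRecord]:
    """Read the drug registry TSV (drug_id, name, atc_codes, superclass).

    ATC codes are semicolon-separated; each must reduce to a valid
    first-level letter.  Duplicate drug IDs and malformed codes are hard
    errors naming the offender.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"drug_id", "name", "atc_codes", "superclass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry missing columns: {sorted(missing)}")
    dupes = df["drug_id"][df["drug_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate drug_id in registry: {dupes}")
    records = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        codes = [c.strip() for c in row.atc_codes.split(";") if c.strip()]
        try:
            for c in codes:
                atc_first_level(c)
        except ValueError as exc:
            raise ValueError(f"row {rownum}: {exc}") from exc
        records.append(
            DrugRecord(
                drug_id=row.drug_id,
                name=row.name,
                atc_codes=frozenset(codes),
                superclass=row.superclass or None,
            )
        )
    return records


def write_drug_registry(records: Iterable[DrugRecord], path: str | Path) -> None:
    rows = [
        {
            "drug_id": r.drug_id,
            "name": r.name,
            "atc_codes": ";".join(sorted(r.atc_codes)),
            "superclass": r.superclass or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_feature_profiles(path: str | Path, kind: str) -> list[FeatureProfile]:
    """Read sparse drug--feature pairs into per-drug profiles.

    Columns: drug_id, feature_token and an optional frequency in [0, 1].
    Duplicate pairs collapse to one set member with a logged warning.
    Drug order follows first appearance in the file.
    """
    if kind not in FEATURE_KINDS:
        raise ValueError(f"unknown profile kind {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, keep_default_na=False)
    if df.shape[1] not in (2, 3):
        raise ValueError("feature-pair file must have 2 or 3 columns")
    has_freq = df.shape[1] == 3
    features: dict[str, set[str]] = {}
    freqs: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        drug, token = row[0], row[1]
        bucket = features.setdefault(drug, set())
        if token in bucket:
            logger.warning("duplicate feature pair (%s, %s)", drug, token)
        bucket.add(token)
        if has_freq and row[2] != "":
            f = float(row[2])
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} outside [0, 1] for ({drug}, {token})")
            freqs.setdefault(drug, {})[token] = f
    return [
        FeatureProfile(d, frozenset(features[d]), kind, freqs.get(d, {}))
        for d in features
    ]


def write_feature_profiles(profiles: Iterable[FeatureProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for token in sorted(p.features):
            row = {"drug_id": p.drug_id, "feature": token}
            if token in p.frequencies:
                row["frequency"] = repr(p.frequencies[token])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_target_map(path: str | Path) -> list[TargetMap]:
    """Read two-column (drug_id, protein_id) pairs into per-drug target sets."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise ValueError("target map file must have 2 columns")
    targets: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        targets.setdefault(row[0], set()).add(row[1])
    return [TargetMap(d, frozenset(p)) for d, p in targets.items()]


def write_target_map(maps: Iterable[TargetMap], path: str | Path) -> None:
    rows = [
        {"drug_id": t.drug_id, "protein_id": pid}
        for t in maps
        for pid in sorted(t.protein_ids)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, scale: str = "unit") -> SimilarityMatrix:
    """Read a dense TSV similarity matrix with drug_id header row/column.

    Asymmetry beyond 1e-9 is an error; smaller numerical asymmetry is
    exactly symmetrized as (M + M')/2.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"matrix is not square: {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("matrix row and column drug_ids differ")
    vals = df.to_numpy(dtype=float)
    gap = np.abs(vals - vals.T).max() if vals.size else 0.0
    if gap > 1e-9:
        raise ValueError(f"matrix asymmetric beyond tolerance: max gap {gap:.3g}")
    vals = (vals + vals.T) / 2.0
    return SimilarityMatrix(list(df.index.astype(str)), vals, scale)


def write_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.drugs, columns=matrix.drugs)
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_cluster_assignment(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "cluster": int})
    return dict(zip(df["drug_id"], df["cluster"]))


def write_cluster_assignment(labels: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"drug_id": list(labels), "cluster": [labels[d] for d in labels]}
    ).to_csv(path, sep="\t", index=False)


def common_drugs(*drug_lists: Sequence[str]) -> list[str]:
    """Intersection of drug lists, ordered as in the first list.

    The fused network is built on drugs present in every property view;
    exclusions are logged with counts.
    """
    if not drug_lists:
        return []
    keep = set(drug_lists[0])
    for lst in drug_lists[1:]:
        keep &= set(lst)
    for i, lst in enumerate(drug_lists):
        dropped = len(lst) - len(keep & set(lst))
        if dropped:
            logger.info("view %d: %d drugs absent from the common set", i, dropped)
    return [d for d in drug_lists[0] if d in keep]
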