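"""Multi-task feature construction and subclass prediction.

A single two-class model covers every EC subclass by featurising each
(sequence, candidate class) pair with the class-mean descriptors ⟨d⟩ and the
deviations D = d(sequence) − ⟨d⟩(class).  An enzyme paired with its own
class carries the label +1; a non-enzyme paired with a candidate class
carries −1.  At prediction time a sequence is scored against every enzyme
class profile and assigned to the best-scoring class if that score clears
the decision threshold, otherwise to "non-enzyme".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorVector
from .seqio import NON_ENZYME, ClassAnnotation

#: descriptor columns used as model features
DEFAULT_DESCRIPTORS: tuple[str, ...] = ("Tr3", "Tr5")

#: pair-feature column order shared with the model layer
FEATURE_COLUMNS: tuple[str, ...] = ("Tr3_mean", "Tr5_mean", "DTr3", "DTr5")

NEGATIVE_POLICIES = ("random-class", "all-classes", "cross-class")


class Scorer(Protocol):
    """Anything that maps a pair-feature mapping to a real decision score."""

    def score(self, features: Mapping[str, float]) -> float: ...


@dataclass
class ClassProfile:
    """Arithmetic descriptor means over the member sequences of one class."""

    class_id: str
    mean: dict[str, float]
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"class {self.class_id!r} has no members")


def compute_class_profiles(
    table: pd.DataFrame, annotations: Sequence[ClassAnnotation]
) -> dict[str, ClassProfile]:
    """One profile per distinct class id (including "non-enzyme").

    ``table`` is a descriptor table with a ``sequence_id`` column; every
    annotated class must have at least one member present in it.
    """
    ann_df = pd.DataFrame(
        [(a.sequence_id, a.class_id) for a in annotations],
        columns=["sequence_id", "class_id"],
    )
    merged = table.merge(ann_df, on="sequence_id", how="inner")
    descriptor_cols = [c for c in table.columns if c != "sequence_id"]
    profiles: dict[str, ClassProfile] = {}
    for class_id in ann_df["class_id"].unique():
        members = merged[merged["class_id"] == class_id]
        if members.empty:
            raise ValueError(
                f"class {class_id!r} has no member sequences in the descriptor table"
            )
        profiles[class_id] = ClassProfile(
            class_id=class_id,
            mean={c: float(members[c].mean()) for c in descriptor_cols},
            count=len(members),
        )
    return profiles


def deviation(
    x: DescriptorVector | Mapping[str, float], profile: ClassProfile
) -> dict[str, float]:
    """Elementwise deviation  D = x − ⟨x⟩(class)  over shared descriptors."""
    values = x.as_row() if isinstance(x, DescriptorVector) else dict(x)
    out: dict[str, float] = {}
    for name, mean in profile.mean.items():
        if name not in values:
            raise KeyError(
                f"descriptor {name!r} missing from input (profile {profile.class_id!r})"
            )
        out[name] = float(values[name]) - mean
    return out


def pair_features(
    x: Mapping[str, float],
    profile: ClassProfile,
    descriptors: tuple[str, ...] = DEFAULT_DESCRIPTORS,
) -> dict[str, float]:
    """Feature mapping ⟨d⟩, D d for one (sequence, candidate class) pair."""
    feats: dict[str, float] = {}
    for d in descriptors:
        feats[f"{d}_mean"] = profile.mean[d]
        feats[f"D{d}"] = float(x[d]) - profile.mean[d]
    return feats


def make_pairs(
    table: pd.DataFrame,
    annotations: Sequence[ClassAnnotation],
    profiles: Mapping[str, ClassProfile],
    negative_policy: str = "random-class",
    seed: int = 0,
    descriptors: tuple[str, ...] = DEFAULT_DESCRIPTORS,
) -> pd.DataFrame:
    """Build the (sequence, candidate class) pair table.

    Each enzyme contributes one +1 record against its annotated class.  Each
    non-enzyme contributes −1 record(s) against candidate enzyme classes
    chosen by ``negative_policy``:

    * ``"random-class"`` (default): one uniformly random enzyme subclass,
      drawn with the given seed — total records = number of sequences;
    * ``"all-classes"``: one record per enzyme subclass;
    * ``"cross-class"``: full activity labelling ε_q(c) for every
      (sequence, subclass) combination — enzymes additionally yield −1
      records against every *other* subclass, which is what a scorer needs
      to learn before it can rank candidate classes per sequence.
    """
    if negative_policy not in NEGATIVE_POLICIES:
        raise ValueError(
            f"unknown negative_policy {negative_policy!r}; expected one of {NEGATIVE_POLICIES}"
        )
    enzyme_classes = sorted(c for c in profiles if c != NON_ENZYME)
    if not enzyme_classes:
        raise ValueError("no enzyme class profiles available")
    rng = np.random.default_rng(seed)
    indexed = table.set_index("sequence_id")
    rows = []
    for ann in annotations:
        x = indexed.loc[ann.sequence_id]
        if ann.is_enzyme:
            candidates = [(ann.class_id, 1)]
            if negative_policy == "cross-class":
                candidates += [(c, -1) for c in enzyme_classes if c != ann.class_id]
        elif negative_policy == "random-class":
            candidates = [(enzyme_classes[rng.integers(len(enzyme_classes))], -1)]
        else:
            candidates = [(c, -1) for c in enzyme_classes]
        for class_id, label in candidates:
            feats = pair_features(x, profiles[class_id], descriptors)
            rows.append(
                {
                    "sequence_id": ann.sequence_id,
                    "class_id": class_id,
                    **feats,
                    "label": label,
                }
            )
    cols = ["sequence_id", "class_id", *FEATURE_COLUMNS, "label"]
    return pd.DataFrame(rows, columns=cols)


def predict_subclass(
    x: DescriptorVector | Mapping[str, float],
    profiles: Mapping[str, ClassProfile],
    model: Scorer,
    threshold: float = 0.0,
    descriptors: tuple[str, ...] = DEFAULT_DESCRIPTORS,
) -> tuple[str, float]:
    """Assign a sequence to an enzyme subclass or "non-enzyme".

    The sequence is scored against every enzyme-class profile; the
    best-scoring class is returned if its score exceeds ``threshold``, else
    "non-enzyme".  Ties go to the lexicographically smallest EC string.
    Returns ``(class_id, best_score)``.
    """
    enzyme_classes = sorted(c for c in profiles if c != NON_ENZYME)
    if not enzyme_classes:
        raise ValueError("no enzyme class profiles to score against")
    values = x.as_row() if isinstance(x, DescriptorVector) else dict(x)
    best_class, best_score = None, -np.inf
    for class_id in enzyme_classes:  # lexicographic order breaks ties
        s = model.score(pair_features(values, profiles[class_id], descriptors))
        if s > best_score:
            best_class, best_score = class_id, s
    assert best_class is not None
    if best_score > threshold:
        return best_class, float(best_score)
    return NON_ENZYME, float(best_score)


def split_pairs(
    pairs: pd.DataFrame, fraction: float = 0.70, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded train/validation split of pair records (default 70/30)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("split fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    n_train = int(round(fraction * len(pairs)))
    train = pairs.iloc[perm[:n_train]].reset_index(drop=True)
    valid = pairs.iloc[perm[n_train:]].reset_index(drop=True)
    return train, valid


def write_profiles(profiles: Mapping[str, ClassProfile], path: str | Path) -> None:
    """Profiles as TSV: class_id, count, then one column per descriptor mean."""
    names = sorted({n for p in profiles.values() for n in p.mean})
    rows = [
        {"class_id": p.class_id, "count": p.count, **p.mean}
        for p in sorted(profiles.values(), key=lambda p: p.class_id)
    ]
    pd.DataFrame(rows, columns=["class_id", "count", *names]).to_csv(
        path, sep="\t", index=False
    )


def read_profiles(path: str | Path) -> dict[str, ClassProfile]:
    df = pd.read_csv(path, sep="\t")
    required = {"class_id", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"profile file {path} lacks columns {sorted(required)}")
    mean_cols = [c for c in df.columns if c not in required]
    return {
        str(row["class_id"]): ClassProfile(
            class_id=str(row["class_id"]),
            mean={c: float(row[c]) for c in mean_cols},
            count=int(row["count"]),
        )
        for _, row in df.iterrows()
    }
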