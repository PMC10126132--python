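"""Airway-topography similarity: paired-profile Hamming statistic and test.

For two tissue types sampled from the same individuals (e.g. exhaled breath
condensate vs bronchoalveolar lavage), the similarity statistic is

    SH = sum_i H(d_i, d_i')

where d_i and d_i' are the binary microRNA profiles of individual i in the two
tissues and H is the Hamming distance.  Small SH means the two tissues carry
similar within-individual microRNA fingerprints.  Significance comes from a
permutation test that breaks the within-individual pairing by reassigning one
tissue's profiles among individuals: the one-sided p-value asks whether the
observed pairing is more similar than random pairings.

Permuting one tissue's profiles over individual labels while holding the other
fixed is distributionally identical to independently permuting the profiles
within each tissue type (relabeling both sides composes to a single random
permutation), so the single-sided scheme is used for efficiency.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TissueProfileSet",
    "SimilarityResult",
    "PermutationResult",
    "hamming",
    "similarity_statistic",
    "permutation_test",
]


def _as_profile(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    ok = np.isnan(a) | (a == 0) | (a == 1)
    if not ok.all():
        raise ValueError("profiles must contain only 0, 1 or missing")
    return a


@dataclass
class TissueProfileSet:
    """Binary microRNA profiles for each individual at several airway levels.

    ``profiles`` maps (individual_id, tissue_code) to a float vector over
    ``mirs`` with values 1, 0 or NaN (missing call).  Not every individual
    needs every tissue.
    """

    individuals: list[str]
    tissues: list[str]
    mirs: list[str]
    profiles: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual ids must be unique")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue codes must be unique")
        clean = {}
        for (ind, tis), vec in self.profiles.items():
            if ind not in self.individuals:
                raise ValueError(f"unknown individual {ind!r}")
            if tis not in self.tissues:
                raise ValueError(f"unknown tissue {tis!r}")
            a = _as_profile(vec)
            if a.shape != (len(self.mirs),):
                raise ValueError(
                    f"profile ({ind}, {tis}) has length {a.shape[0]}, expected {len(self.mirs)}"
                )
            clean[(ind, tis)] = a
        self.profiles = clean

    def profile(self, individual: str, tissue: str) -> np.ndarray | None:
        return self.profiles.get((individual, tissue))

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for (ind, tis), vec in self.profiles.items():
            for mir, v in zip(self.mirs, vec):
                rows.append(
                    {
                        "individual_id": ind,
                        "tissue": tis,
                        "mir_id": mir,
                        "call": pd.NA if math.isnan(v) else int(v),
                    }
                )
        return pd.DataFrame(rows, columns=["individual_id", "tissue", "mir_id", "call"])

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "TissueProfileSet":
        required = {"individual_id", "tissue", "mir_id", "call"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"profile table missing columns: {sorted(missing)}")
        individuals = list(pd.unique(df["individual_id"].astype(str)))
        tissues = list(pd.unique(df["tissue"].astype(str)))
        mirs = list(pd.unique(df["mir_id"].astype(str)))
        mir_index = {m: j for j, m in enumerate(mirs)}
        profiles: dict[tuple[str, str], np.ndarray] = {}
        for (ind, tis), grp in df.groupby(["individual_id", "tissue"], sort=False):
            vec = np.full(len(mirs), np.nan)
            for _, row in grp.iterrows():
                call = row["call"]
                vec[mir_index[str(row["mir_id"])]] = (
                    np.nan if pd.isna(call) else float(int(call))
                )
            profiles[(str(ind), str(tis))] = vec
        return cls(individuals=individuals, tissues=tissues, mirs=mirs, profiles=profiles)


def hamming(profile_a, profile_b, *, return_effective_length: bool = False):
    """Hamming distance between two binary profiles.

    Positions missing (NaN) in either profile are excluded from the count;
    with ``return_effective_length=True`` the number of compared positions is
    returned alongside.
    """
    a = _as_profile(profile_a)
    b = _as_profile(profile_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    mask = ~(np.isnan(a) | np.isnan(b))
    d = int(np.sum(a[mask] != b[mask]))
    if return_effective_length:
        return d, int(mask.sum())
    return d


@dataclass(frozen=True)
class SimilarityResult:
    """SH with its per-individual decomposition and coverage report."""

    sh: int
    tissue_pair: tuple[str, str]
    contributions: dict[str, int]  # individual -> Hamming distance
    effective_lengths: dict[str, int]  # individual -> positions compared
    individuals_used: list[str]
    individuals_skipped: list[str]  # lacked a profile in one of the tissues

    def __int__(self) -> int:
        return self.sh


def _usable_individuals(
    pset: TissueProfileSet, tissue_a: str, tissue_b: str, strict: bool
) -> tuple[list[str], list[str]]:
    for t in (tissue_a, tissue_b):
        if t not in pset.tissues:
            raise ValueError(f"tissue {t!r} not in profile set (has {pset.tissues})")
    used, skipped = [], []
    for ind in pset.individuals:
        a = pset.profile(ind, tissue_a)
        b = pset.profile(ind, tissue_b)
        if a is None or b is None:
            skipped.append(ind)
        elif strict and (np.isnan(a).any() or np.isnan(b).any()):
            skipped.append(ind)
        else:
            used.append(ind)
    return used, skipped


def similarity_statistic(
    pset: TissueProfileSet,
    tissue_a: str,
    tissue_b: str,
    *,
    strict_missing: bool = False,
) -> SimilarityResult:
    """SH = sum over individuals of the Hamming distance between their two
    tissue profiles.

    Individuals lacking either profile are skipped (reported in the result).
    Missing calls are excluded pairwise; ``strict_missing=True`` instead drops
    any individual with a missing call in either profile.
    """
    used, skipped = _usable_individuals(pset, tissue_a, tissue_b, strict_missing)
    if not used:
        raise ValueError(
            f"no individual has both {tissue_a} and {tissue_b} profiles"
        )
    contributions, lengths = {}, {}
    for ind in used:
        d, n = hamming(
            pset.profile(ind, tissue_a),
            pset.profile(ind, tissue_b),
            return_effective_length=True,
        )
        contributions[ind] = d
        lengths[ind] = n
    return SimilarityResult(
        sh=int(sum(contributions.values())),
        tissue_pair=(tissue_a, tissue_b),
        contributions=contributions,
        effective_lengths=lengths,
        individuals_used=used,
        individuals_skipped=skipped,
    )


@dataclass(frozen=True)
class PermutationResult:
    observed_sh: int
    n_permutations: int
    n_as_or_more_similar: int
    p_value: float
    tissue_pair: tuple[str, str]
    seed: int | None
    exhaustive: bool
    #: plug-in estimate count/B (reported alongside; the add-one estimator is
    #: the headline p so Monte-Carlo p is never exactly 0)
    p_value_plugin: float = float("nan")


def _pairwise_sh_matrix(
    pset: TissueProfileSet, used: Sequence[str], tissue_a: str, tissue_b: str
) -> np.ndarray:
    """D[i, j] = Hamming(profile_i in tissue_a, profile_j in tissue_b).

    SH under a permutation pi of tissue-b profiles is sum_i D[i, pi(i)], so
    the null distribution reduces to row-indexed sums of this matrix.
    """
    A = np.stack([pset.profile(i, tissue_a) for i in used])
    B = np.stack([pset.profile(i, tissue_b) for i in used])
    n = len(used)
    D = np.zeros((n, n), dtype=float)
    for i in range(n):
        a = A[i]
        mask = ~(np.isnan(a)[None, :] | np.isnan(B))
        D[i] = np.sum((a[None, :] != B) & mask, axis=1)
    return D


def permutation_test(
    pset: TissueProfileSet,
    tissue_a: str,
    tissue_b: str,
    n_permutations: int = 1000,
    seed: int | None = None,
    exhaustive_threshold: int = 7,
    *,
    strict_missing: bool = False,
) -> PermutationResult:
    """One-sided permutation test of within-individual tissue similarity.

    The null reassigns tissue-b profiles to individuals uniformly at random
    (tissue-a fixed); small SH is evidence the pairing matters.  Ties count as
    "as or more similar" (conservative).  For n individuals at or below
    ``exhaustive_threshold`` all n! assignments are enumerated and the p-value
    is exact; otherwise ``n_permutations`` Monte-Carlo draws are taken and the
    add-one estimator (count + 1) / (B + 1) is reported.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    used, _ = _usable_individuals(pset, tissue_a, tissue_b, strict_missing)
    if not used:
        raise ValueError(f"no individual has both {tissue_a} and {tissue_b} profiles")
    D = _pairwise_sh_matrix(pset, used, tissue_a, tissue_b)
    n = len(used)
    observed = int(np.trace(D))
    rows = np.arange(n)

    if n <= exhaustive_threshold:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if D[rows, perm].sum() <= observed:
                count += 1
        p = count / total
        return PermutationResult(
            observed_sh=observed,
            n_permutations=total,
            n_as_or_more_similar=count,
            p_value=p,
            tissue_pair=(tissue_a, tissue_b),
            seed=seed,
            exhaustive=True,
            p_value_plugin=p,
        )

    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, n), dtype=np.intp)
    for k in range(n_permutations):
        perms[k] = rng.permutation(n)
    null_sh = D[rows[None, :], perms].sum(axis=1)
    count = int(np.sum(null_sh <= observed))
    return PermutationResult(
        observed_sh=observed,
        n_permutations=n_permutations,
        n_as_or_more_similar=count,
        p_value=(count + 1) / (n_permutations + 1),
        tissue_pair=(tissue_a, tissue_b),
        seed=seed,
        exhaustive=False,
        p_value_plugin=count / n_permutations,
    )
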