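"""Qualitative scoring of SYBR-green realtime PCR wells into microRNA calls.

MicroRNAs are near-identical in size, so amplicon identity rests on the melt
temperature: a well is called *positive* only when its melt temperature matches
the positive-control Tm for that primerset (within a tolerance) and its Ct is
below the positivity cutoff.  A sample is positive for a microRNA when at
least one of its replicate wells is positive.  Clinical data are strictly
qualitative (present/absent); the delta-Ct matrix is used only for the
temporal-stability QC sub-analysis.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .panels import HOUSEKEEPER_ID, normalize_mir_id

logger = logging.getLogger(__name__)

__all__ = [
    "WellRecord",
    "ScoringConfig",
    "MirCall",
    "MirCallMatrix",
    "MissingReferenceTmError",
    "call_well",
    "call_sample",
    "build_call_matrix",
    "delta_ct_matrix",
    "fold_sensitivity",
    "amplicon_length",
    "SpecificityResult",
    "specificity_delta_ct",
]

Call = Literal["positive", "negative"]


class MissingReferenceTmError(ValueError):
    """No positive-control melt temperature is known for a primerset."""

    def __init__(self, mir_id: str):
        super().__init__(
            f"No reference Tm available for primerset {mir_id!r}; a well "
            "cannot be scored without its positive-control melt temperature."
        )
        self.mir_id = mir_id


def _is_absent(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class WellRecord:
    """One realtime-PCR well.

    ``ct`` is the cycle threshold (absent = no amplification within the run);
    ``tm`` is the product melt temperature (absent = no visible melt curve).
    """

    sample_id: str
    mir_id: str
    replicate_index: int = 1
    ct: float | None = None
    tm: float | None = None
    is_positive_control: bool = False

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        if not _is_absent(self.ct) and self.ct <= 0:
            raise ValueError(f"ct must be positive, got {self.ct}")
        if not _is_absent(self.tm) and not (50.0 < self.tm < 100.0):
            raise ValueError(f"tm must lie in (50, 100) degC, got {self.tm}")


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds for qualitative scoring.

    The clinical runs use 45 cycles with positivity requiring Ct < 44; the
    temporal-stability sub-study uses a 40-cycle program with a housekeeper
    Ct cutoff of 35.  Both regimes are expressible here; nothing is
    hard-coded.
    """

    tm_tolerance: float = 1.5  # degC, inclusive
    ct_positive_max: float = 44.0  # cycles, strict upper bound
    total_cycles: int = 45
    replicate_rule: str = "any_of_replicates"
    housekeeper_id: str = HOUSEKEEPER_ID
    housekeeper_ct_max: float = 35.0

    def __post_init__(self) -> None:
        if self.tm_tolerance <= 0:
            raise ValueError("tm_tolerance must be > 0")
        if not (0 < self.housekeeper_ct_max <= self.ct_positive_max <= self.total_cycles):
            raise ValueError(
                "require 0 < housekeeper_ct_max <= ct_positive_max <= total_cycles, "
                f"got {self.housekeeper_ct_max}, {self.ct_positive_max}, {self.total_cycles}"
            )
        if self.replicate_rule != "any_of_replicates":
            raise ValueError(f"unknown replicate_rule {self.replicate_rule!r}")


@dataclass(frozen=True)
class MirCall:
    """Qualitative call for one (sample, microRNA) pair."""

    sample_id: str
    mir_id: str
    call: Call
    n_replicates: int
    n_positive_replicates: int


def call_well(well: WellRecord, reference_tm: float, config: ScoringConfig | None = None) -> Call:
    """Score a single well positive or negative.

    Positive requires: a visible melt curve whose Tm is within
    ``tm_tolerance`` of the positive-control Tm for this primerset
    (inclusive), and a Ct strictly below ``ct_positive_max``.  Everything
    else — no amplification, no melt curve, off-temperature product — is
    negative.
    """
    config = config or ScoringConfig()
    if _is_absent(reference_tm):
        raise MissingReferenceTmError(well.mir_id)
    if _is_absent(well.ct) or _is_absent(well.tm):
        return "negative"
    if abs(well.tm - reference_tm) > config.tm_tolerance:
        return "negative"
    if well.ct >= config.ct_positive_max:
        return "negative"
    return "positive"


def call_sample(
    wells: Sequence[WellRecord],
    reference_tm: float,
    config: ScoringConfig | None = None,
) -> MirCall:
    """Aggregate replicate wells for one (sample, microRNA) into one call.

    The scoring convention is "at least one of n replicates positive"
    (the study ran duplicates; the rule generalizes to any replicate count,
    which is recorded in the result).
    """
    config = config or ScoringConfig()
    if len(wells) == 0:
        raise ValueError("call_sample requires at least one well")
    sample_ids = {w.sample_id for w in wells}
    mir_ids = {w.mir_id for w in wells}
    if len(sample_ids) != 1 or len(mir_ids) != 1:
        raise ValueError(
            f"wells must share one (sample, mir): got samples {sorted(sample_ids)}, "
            f"mirs {sorted(mir_ids)}"
        )
    n_pos = sum(call_well(w, reference_tm, config) == "positive" for w in wells)
    return MirCall(
        sample_id=wells[0].sample_id,
        mir_id=wells[0].mir_id,
        call="positive" if n_pos >= 1 else "negative",
        n_replicates=len(wells),
        n_positive_replicates=n_pos,
    )


@dataclass
class MirCallMatrix:
    """Binary present/absent calls, samples x microRNAs, missing allowed.

    Backed by a pandas DataFrame with nullable-integer cells (1 / 0 / pd.NA),
    index = sample ids, columns = the microRNA panel in its given order.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = self.calls.astype("Int64")
        bad = self.calls.stack().dropna()
        if not bad.isin([0, 1]).all():
            raise ValueError("call matrix cells must be 1, 0 or missing")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def mirs(self) -> list[str]:
        return list(self.calls.columns)

    def to_csv(self, path) -> None:
        out = self.calls.copy()
        out.index.name = "sample_id"
        out.to_csv(path, na_rep="NA")

    @classmethod
    def from_csv(cls, path) -> "MirCallMatrix":
        df = pd.read_csv(path, index_col="sample_id", na_values=["NA"], keep_default_na=False)
        return cls(calls=df)


def build_call_matrix(calls: Iterable[MirCall], mir_panel: Sequence[str]) -> MirCallMatrix:
    """Assemble per-(sample, mir) calls into a samples x panel matrix.

    Cells with no call are missing.  Column order follows the given panel;
    row order is sample order of first appearance.  Duplicate (sample, mir)
    pairs are an error — replicate aggregation happens in ``call_sample``.
    """
    calls = list(calls)
    pairs = Counter((c.sample_id, c.mir_id) for c in calls)
    dups = sorted(p for p, k in pairs.items() if k > 1)
    if dups:
        raise ValueError(f"duplicate (sample, mir) calls: {dups}")
    samples: list[str] = []
    seen = set()
    for c in calls:
        if c.sample_id not in seen:
            seen.add(c.sample_id)
            samples.append(c.sample_id)
    df = pd.DataFrame(pd.NA, index=samples, columns=list(mir_panel), dtype="Int64")
    for c in calls:
        if c.mir_id in df.columns:
            df.loc[c.sample_id, c.mir_id] = 1 if c.call == "positive" else 0
    return MirCallMatrix(calls=df)


def delta_ct_matrix(
    wells: Sequence[WellRecord],
    targets: Sequence[str],
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Delta-Ct per (sample, target): Ct(target) - Ct(housekeeper).

    Replicate Cts are averaged over amplified wells.  A cell is missing when
    the target never amplified, the housekeeper never amplified, or the
    housekeeper Ct exceeds ``housekeeper_ct_max`` (an unreliable housekeeper
    invalidates normalization for that sample).  A sample with no housekeeper
    wells at all yields a missing row and a logged warning.
    """
    config = config or ScoringConfig()
    hk = normalize_mir_id(config.housekeeper_id)
    samples: list[str] = []
    for w in wells:
        if w.sample_id not in samples:
            samples.append(w.sample_id)

    def mean_ct(sub: list[WellRecord]) -> float:
        cts = [w.ct for w in sub if not _is_absent(w.ct)]
        return float(np.mean(cts)) if cts else math.nan

    out = pd.DataFrame(np.nan, index=samples, columns=list(targets), dtype=float)
    for s in samples:
        sample_wells = [w for w in wells if w.sample_id == s]
        hk_wells = [w for w in sample_wells if normalize_mir_id(w.mir_id) == hk]
        if not hk_wells:
            logger.warning("sample %s has no housekeeper (%s) wells; row left missing", s, hk)
            continue
        hk_ct = mean_ct(hk_wells)
        if math.isnan(hk_ct) or hk_ct > config.housekeeper_ct_max:
            continue
        for t in targets:
            t_norm = normalize_mir_id(t)
            t_wells = [w for w in sample_wells if normalize_mir_id(w.mir_id) == t_norm]
            t_ct = mean_ct(t_wells)
            if not math.isnan(t_ct):
                out.loc[s, t] = t_ct - hk_ct
    return out


def fold_sensitivity(ct_a: float, ct_b: float) -> float:
    """Fold sensitivity advantage of platform A over B assuming perfect
    doubling per cycle: 2**(ct_b - ct_a).

    E.g. Ct 27 on one platform vs 31 on another implies a 2**4 = 16-fold
    advantage for the first.
    """
    if _is_absent(ct_a) or _is_absent(ct_b):
        raise ValueError("both Ct values must be present")
    return float(2.0 ** (ct_b - ct_a))


def amplicon_length(mir_length_nt: int, tag_length_bp: int) -> int:
    """PCR product length for a universal-tag RT design: the microRNA
    template plus the integrated tag (e.g. 22 nt + 40 bp tag = 62 bp)."""
    if mir_length_nt <= 0 or tag_length_bp <= 0:
        raise ValueError("lengths must be positive")
    return int(mir_length_nt) + int(tag_length_bp)


class SpecificityResult(NamedTuple):
    delta_ct: float
    censored: bool


def specificity_delta_ct(
    ct_with_polya: float | None,
    ct_without_polya: float | None,
    total_cycles: int = 45,
) -> SpecificityResult:
    """MicroRNA-specificity of a primerset from the polyadenylation screen.

    Returns Ct(no-polyA condition) - Ct(polyA condition); the larger the
    difference, the more microRNA-specific the primerset (mRNA-derived signal
    would amplify without the polyA step).  A condition that never amplified
    is censored at ``total_cycles`` and flagged.
    """
    a_absent = _is_absent(ct_with_polya)
    b_absent = _is_absent(ct_without_polya)
    if a_absent and b_absent:
        raise ValueError("at least one condition must have amplified")
    censored = a_absent or b_absent
    ct_a = float(total_cycles) if a_absent else float(ct_with_polya)
    ct_b = float(total_cycles) if b_absent else float(ct_without_polya)
    return SpecificityResult(delta_ct=ct_b - ct_a, censored=censored)
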