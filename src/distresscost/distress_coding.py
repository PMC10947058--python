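"""Kessler-10 scoring, distress levels, onset/chronicity samples and balanced panels.

The Kessler Psychological Distress Scale (K10) is the sum of ten items each
scored 1-5, giving a total in [10, 50]; higher scores mean more distress.
Scores are categorised into four levels -- none (10-19), mild (20-24),
moderate (25-29) and severe (30-50) -- and a binary "distressed" indicator is
defined as K10 > 24 (i.e. moderate or severe).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LEVELS = ("none", "mild", "moderate", "severe")


@dataclass(frozen=True)
class DistressCutoffs:
    """Score boundaries for the four distress levels and the binary dummy.

    ``none_max``/``mild_max``/``moderate_max`` are the inclusive upper bounds
    of the first three levels; everything above ``moderate_max`` up to
    ``max_score`` is severe.  ``dummy_threshold`` defines the binary
    indicator as ``score > dummy_threshold``.
    """

    none_max: int = 19
    mild_max: int = 24
    moderate_max: int = 29
    min_score: int = 10
    max_score: int = 50
    dummy_threshold: int = 24

    def __post_init__(self) -> None:
        seq = (self.min_score, self.none_max, self.mild_max,
               self.moderate_max, self.max_score)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"cutoffs must be strictly increasing within "
                             f"[{self.min_score}, {self.max_score}]: {seq}")
        if not (self.min_score <= self.dummy_threshold < self.max_score):
            raise ValueError("dummy_threshold out of score range")


DEFAULT_CUTOFFS = DistressCutoffs()


def k10_score(responses: Sequence[int]) -> int:
    """Sum of the ten item responses (each 1-5); total in [10, 50]."""
    responses = list(responses)
    if len(responses) != 10:
        raise ValueError(f"expected exactly 10 item responses, got {len(responses)}")
    for i, r in enumerate(responses):
        if not (isinstance(r, (int, np.integer)) and 1 <= r <= 5):
            raise ValueError(f"item {i + 1} response {r!r} not an integer in [1, 5]")
    return int(sum(responses))


def _check_scores(scores: np.ndarray, cutoffs: DistressCutoffs) -> None:
    bad = (scores < cutoffs.min_score) | (scores > cutoffs.max_score)
    if np.any(bad):
        raise ValueError(
            f"K10 score(s) outside [{cutoffs.min_score}, {cutoffs.max_score}]: "
            f"{np.asarray(scores)[bad][:5]}")


def k10_level(score: int, cutoffs: DistressCutoffs = DEFAULT_CUTOFFS) -> str:
    """Distress level label for one score."""
    return str(k10_levels([score], cutoffs)[0])


def k10_levels(scores: Iterable[int],
               cutoffs: DistressCutoffs = DEFAULT_CUTOFFS) -> np.ndarray:
    """Vectorised level assignment; partitions [min_score, max_score] exactly."""
    s = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores)
    _check_scores(s, cutoffs)
    bins = [cutoffs.none_max, cutoffs.mild_max, cutoffs.moderate_max]
    idx = np.searchsorted(bins, s, side="left")  # score <= bound -> that level
    return np.asarray(LEVELS, dtype=object)[idx]


def distress_dummy(score, cutoffs: DistressCutoffs = DEFAULT_CUTOFFS):
    """Binary indicator: 1 iff score strictly exceeds the dummy threshold (>24)."""
    s = np.asarray(score)
    _check_scores(np.atleast_1d(s), cutoffs)
    out = (s > cutoffs.dummy_threshold).astype(int)
    return int(out) if np.isscalar(score) or s.ndim == 0 else out


def balance_panel(panel: pd.DataFrame, required_waves: Sequence[int]) -> pd.DataFrame:
    """Keep only women observed in every wave of ``required_waves``.

    Emits a warning (via ``warnings``) rather than an error when the result
    is empty.
    """
    required = set(int(w) for w in required_waves)
    observed = panel.groupby("id")["wave"].agg(lambda w: required <= set(w.astype(int)))
    keep_ids = observed[observed].index
    out = panel[panel["id"].isin(keep_ids) & panel["wave"].isin(required)].copy()
    if out.empty:
        import warnings
        warnings.warn("balanced panel is empty for the requested waves")
    return out


@dataclass
class ChronicityFlags:
    """Per-woman onset/persistence flags over the post-baseline waves.

    ``onset_any`` means distress in at least one of waves 2..W, ``at_least_2``
    / ``at_least_3`` / ``all_4`` count distressed waves among waves 2..W (the
    baseline wave is distress-free by construction of the onset sample).
    Flags nest: all_4 => at_least_3 => at_least_2 => onset_any.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        ok = ((~t["all_4"] | t["at_least_3"]) & (~t["at_least_3"] | t["at_least_2"])
              & (~t["at_least_2"] | t["onset_any"]))
        if not bool(ok.all()):
            raise AssertionError("chronicity flags do not nest")


def build_onset_sample(panel: pd.DataFrame,
                       cutoffs: DistressCutoffs = DEFAULT_CUTOFFS
                       ) -> tuple[pd.DataFrame, ChronicityFlags]:
    """Onset/chronicity sample from a balanced panel.

    Drops women distressed in *every* wave and women distressed at wave 1;
    for the survivors, counts distressed waves among waves 2..W and sets the
    nested chronicity flags.  Input must be balanced (same wave set for every
    woman).
    """
    waves = sorted(panel["wave"].unique())
    counts = panel.groupby("id")["wave"].nunique()
    if counts.nunique() != 1 or counts.iloc[0] != len(waves):
        raise ValueError("build_onset_sample requires a balanced panel")
    first_wave = waves[0]
    d = panel.assign(_dist=distress_dummy(panel["k10"].to_numpy(), cutoffs))
    per_woman = d.pivot(index="id", columns="wave", values="_dist")
    all_waves_distressed = per_woman.sum(axis=1) == len(waves)
    wave1_distressed = per_woman[first_wave] == 1
    kept = ~(all_waves_distressed | wave1_distressed)
    post = per_woman.loc[:, [w for w in waves if w != first_wave]]
    n_post = post.sum(axis=1)
    flags = pd.DataFrame({
        "onset_any": n_post >= 1,
        "at_least_2": n_post >= 2,
        "at_least_3": n_post >= 3,
        "all_4": n_post >= len(waves) - 1,
        "kept_in_sample": kept,
    })
    sample = panel[panel["id"].isin(kept[kept].index)].drop(columns="_dist", errors="ignore")
    return sample.copy(), ChronicityFlags(flags)
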