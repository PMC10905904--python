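"""Domain types, CSV I/O, rating scoring, trial scheduling and count tabulation.

The experiment this package analyses has two parts:

* a *superiority rating* questionnaire — 60 trait words (26 desirable,
  26 undesirable, 8 filler) each rated on a visual-analog scale in
  [-1, 1] with step 0.05, comparing oneself to an imagined average peer;
* a *same/different size-discrimination task* with confidence ratings —
  320 trials split over two background conditions (uniform ``control``
  background vs. a linear-perspective ``depth``-cue background), where the
  to-be-judged disc pair is physically equal (128 trials), 20% different
  (128 trials) or 5% different (64 filler trials, never analysed).

Everything downstream (type-1 SDT, meta-d', hierarchical models, the
regularized-regression stage) consumes either the scored 52-item rating
vector or the response-conditional confidence count tables built here.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Condition",
    "Stimulus",
    "Response",
    "ItemClass",
    "TrialRecord",
    "RatingSheet",
    "ScoredRatings",
    "ConfidenceCountTable",
    "PipelineConfig",
    "ValidationError",
    "trait_items",
    "score_ratings",
    "build_trial_schedule",
    "tabulate_counts",
    "exclude_fillers",
    "read_trials",
    "write_trials",
    "read_ratings",
    "write_ratings",
    "reference_loadings",
    "reference_importance",
]

#: size ratios of the "distant" disc relative to the other disc
ANALYZED_RATIOS = (1.00, 0.80)
FILLER_RATIOS = (0.95, 1.05)
N_CONFIDENCE_LEVELS = 4
VAS_STEP = 0.05


class ValidationError(ValueError):
    """Raised when an input file or record violates the task's contracts."""


class Condition(str, Enum):
    CONTROL = "control"
    DEPTH = "depth"


class Stimulus(str, Enum):
    SAME = "same"
    DIFFERENT = "different"


Response = Stimulus  # responses use the same two labels


class ItemClass(str, Enum):
    DESIRABLE = "desirable"
    UNDESIRABLE = "undesirable"
    FILLER = "filler"


@dataclass(frozen=True)
class TrialRecord:
    """One same/different trial with its confidence rating.

    ``size_ratio`` is the diameter of the contextually "distant" disc relative
    to the other disc; 0.95/1.05 trials are fillers and excluded from every
    analysis. ``response``/``confidence`` may be ``None`` on schedule stubs.
    """

    subject_id: str
    condition: Condition
    stimulus: Stimulus
    size_ratio: float
    response: Response | None = None
    confidence: int | None = None
    is_filler: bool = False

    def __post_init__(self) -> None:
        if self.size_ratio not in ANALYZED_RATIOS + FILLER_RATIOS:
            raise ValidationError(f"size_ratio {self.size_ratio} not a task ratio")
        expected_filler = self.size_ratio in FILLER_RATIOS
        if self.is_filler != expected_filler:
            raise ValidationError(
                f"is_filler={self.is_filler} inconsistent with size_ratio {self.size_ratio}"
            )
        if self.confidence is not None and self.confidence not in (1, 2, 3, 4):
            raise ValidationError(f"confidence {self.confidence} outside 1-4")


def _on_grid(score: float) -> bool:
    return abs(score) <= 1.0 + 1e-9 and abs(round(score / VAS_STEP) * VAS_STEP - score) < 1e-9


@dataclass
class RatingSheet:
    """One subject's raw trait-word ratings (before reverse-coding)."""

    subject_id: str
    scores: dict[str, float]
    classes: dict[str, ItemClass]

    def validate(self) -> None:
        if set(self.scores) != set(self.classes):
            raise ValidationError("scores and classes name different items")
        counts = {cls: 0 for cls in ItemClass}
        for word, cls in self.classes.items():
            counts[ItemClass(cls)] += 1
        if counts[ItemClass.DESIRABLE] != 26 or counts[ItemClass.UNDESIRABLE] != 26 \
                or counts[ItemClass.FILLER] != 8:
            raise ValidationError(
                f"item counts {counts} != 26 desirable + 26 undesirable + 8 filler"
            )
        for word, score in self.scores.items():
            if not _on_grid(score):
                raise ValidationError(
                    f"item {word!r}: score {score} off the 0.05 VAS grid in [-1, 1]"
                )


@dataclass
class ScoredRatings:
    """The 52 scored items (undesirable reverse-coded, fillers dropped)."""

    subject_id: str
    words: list[str]
    values: np.ndarray
    si_score: float  # mean of the 52 scored values; the superiority index

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.words, name=self.subject_id)


@dataclass
class ConfidenceCountTable:
    """Response-conditional confidence counts in the standard type-2 layout.

    ``s1``/``s2`` are length-8 vectors for the two stimulus classes
    ("same" = S1, physically equal discs; "different" = S2, 20% smaller).
    Cell order runs from confidence-4 "same" responses down to confidence-1
    "same", then confidence-1 "different" up to confidence-4 "different":

        index: 0..3  -> response "same",      confidence 4,3,2,1
        index: 4..7  -> response "different", confidence 1,2,3,4
    """

    s1: np.ndarray
    s2: np.ndarray
    n_levels: int = N_CONFIDENCE_LEVELS

    def __post_init__(self) -> None:
        self.s1 = np.asarray(self.s1, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        k = 2 * self.n_levels
        if self.s1.shape != (k,) or self.s2.shape != (k,):
            raise ValidationError(f"count vectors must have length {k}")
        if (self.s1 < 0).any() or (self.s2 < 0).any():
            raise ValidationError("negative cell count")

    @property
    def n_s1(self) -> float:
        return float(self.s1.sum())

    @property
    def n_s2(self) -> float:
        return float(self.s2.sum())


@dataclass
class PipelineConfig:
    """Run-wide settings shared by the CLI subcommands."""

    seed: int = 0
    chains: int = 3
    samples: int = 10_000
    burn_in: int = 1_000
    n_random_parallel: int = 1_000
    parallel_quantile: float = 0.95
    trials_path: str | None = None
    ratings_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValidationError("chains must be >= 1")
        if not (self.samples > self.burn_in >= 0):
            raise ValidationError("need samples > burn_in >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


# ---------------------------------------------------------------------------
# packaged item metadata and published reference tables
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("ponzometa.data").joinpath(name)


def trait_items() -> pd.DataFrame:
    """The 52 scored trait words (item_id, word, valence), in item order."""
    with importlib.resources.as_file(_data_path("trait_items.csv")) as p:
        return pd.read_csv(p)


def reference_loadings() -> pd.DataFrame:
    """Published three-component loadings for the 52 trait items.

    Reference values from the original study of this task battery; used only
    as a printed-table oracle for the weighted-total-importance product, never
    as a substitute for a computed decomposition.
    """
    with importlib.resources.as_file(_data_path("reference_loadings.csv")) as p:
        return pd.read_csv(p)


def reference_importance() -> pd.DataFrame:
    """Published feature importances of the two prediction models (see above)."""
    with importlib.resources.as_file(_data_path("reference_importance.csv")) as p:
        return pd.read_csv(p)


FILLER_WORDS = tuple(f"filler_{i:02d}" for i in range(1, 9))
"""Placeholder filler labels; the original filler words are not published."""


# ---------------------------------------------------------------------------
# rating scoring
# ---------------------------------------------------------------------------

def score_ratings(sheet: RatingSheet) -> ScoredRatings:
    """Drop fillers, reverse-code undesirable items, average into the SI score.

    Scores above zero indicate subjective superiority over the average peer on
    the scored (superiority-coded) scale.
    """
    sheet.validate()
    items = trait_items()
    known = dict(zip(items["word"], items["valence"]))
    words: list[str] = []
    values: list[float] = []
    # canonical order: packaged item order for known words, then extras sorted
    ordered = [w for w in items["word"] if w in sheet.scores]
    extras = sorted(
        w for w, c in sheet.classes.items()
        if ItemClass(c) != ItemClass.FILLER and w not in known
    )
    for word in ordered + extras:
        cls = ItemClass(sheet.classes[word])
        if cls == ItemClass.FILLER:
            continue
        raw = sheet.scores[word]
        values.append(-raw if cls == ItemClass.UNDESIRABLE else raw)
        words.append(word)
    if len(words) != 52:
        raise ValidationError(f"expected 52 scored items, got {len(words)}")
    arr = np.asarray(values, dtype=float)
    return ScoredRatings(sheet.subject_id, words, arr, float(arr.mean()))


def reverse_code(value: float) -> float:
    """Reverse-coding on the VAS scale; an involution (its own inverse)."""
    return -value


# ---------------------------------------------------------------------------
# trial scheduling
# ---------------------------------------------------------------------------

def build_trial_schedule(seed: int, subject_id: str = "S") -> list[TrialRecord]:
    """Pseudo-randomized 320-trial schedule (stubs without responses).

    Per background condition: 64 equal (ratio 1.00), 64 at 0.80, 16 at 0.95
    and 16 at 1.05. The order is randomized within consecutive 40-trial
    blocks, each block containing every condition x size-ratio cell in its
    per-block proportion, so all conditions appear in every 40 trials.
    """
    rng = np.random.default_rng(seed)
    block_cells: list[tuple[Condition, float]] = []
    per_block = {1.00: 8, 0.80: 8, 0.95: 2, 1.05: 2}  # x2 conditions = 40
    for cond in (Condition.CONTROL, Condition.DEPTH):
        for ratio, n in per_block.items():
            block_cells.extend([(cond, ratio)] * n)
    schedule: list[TrialRecord] = []
    for _ in range(8):  # 8 blocks of 40 = 320 trials
        order = rng.permutation(len(block_cells))
        for idx in order:
            cond, ratio = block_cells[idx]
            schedule.append(
                TrialRecord(
                    subject_id=subject_id,
                    condition=cond,
                    stimulus=Stimulus.SAME if ratio == 1.00 else Stimulus.DIFFERENT,
                    size_ratio=ratio,
                    is_filler=ratio in FILLER_RATIOS,
                )
            )
    return schedule


def exclude_fillers(trials: Iterable[TrialRecord]) -> list[TrialRecord]:
    return [t for t in trials if not t.is_filler]


# ---------------------------------------------------------------------------
# count tabulation
# ---------------------------------------------------------------------------

def tabulate_counts(
    trials: Sequence[TrialRecord], condition: Condition | str
) -> ConfidenceCountTable:
    """Build the 2 x (2 x 4) response-conditional confidence count table.

    Input trials must be filler-free and carry responses; only trials of the
    requested background condition are counted.
    """
    condition = Condition(condition)
    k = N_CONFIDENCE_LEVELS
    s1 = np.zeros(2 * k)
    s2 = np.zeros(2 * k)
    for t in trials:
        if t.is_filler:
            raise ValidationError("filler trial passed to tabulate_counts")
        if Condition(t.condition) != condition:
            continue
        if t.response is None or t.confidence is None:
            raise ValidationError("trial without response/confidence")
        if Response(t.response) == Response.SAME:
            idx = k - t.confidence  # conf 4 -> 0 ... conf 1 -> 3
        else:
            idx = k - 1 + t.confidence  # conf 1 -> 4 ... conf 4 -> 7
        if Stimulus(t.stimulus) == Stimulus.SAME:
            s1[idx] += 1
        else:
            s2[idx] += 1
    return ConfidenceCountTable(s1, s2)


def tabulate_all(
    trials: pd.DataFrame | Sequence[TrialRecord],
) -> dict[tuple[str, Condition], ConfidenceCountTable]:
    """Tables for every subject x condition, fillers excluded first."""
    if isinstance(trials, pd.DataFrame):
        trials = frame_to_trials(trials)
    trials = exclude_fillers(trials)
    out: dict[tuple[str, Condition], ConfidenceCountTable] = {}
    subjects = sorted({t.subject_id for t in trials})
    for sid in subjects:
        sub = [t for t in trials if t.subject_id == sid]
        for cond in (Condition.CONTROL, Condition.DEPTH):
            out[(sid, cond)] = tabulate_counts(sub, cond)
    return out


# ---------------------------------------------------------------------------
# CSV I/O (UTF-8, comma-separated, header row, one record per row)
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "subject_id", "condition", "stimulus", "size_ratio",
    "response", "confidence", "is_filler",
]
RATING_COLUMNS = ["subject_id", "item_id", "word", "item_class", "raw_score"]


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": t.subject_id,
            "condition": Condition(t.condition).value,
            "stimulus": Stimulus(t.stimulus).value,
            "size_ratio": t.size_ratio,
            "response": Response(t.response).value if t.response is not None else "",
            "confidence": t.confidence if t.confidence is not None else "",
            "is_filler": t.is_filler,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    trials = []
    for row in frame.itertuples(index=False):
        resp = getattr(row, "response", "")
        conf = getattr(row, "confidence", "")
        trials.append(
            TrialRecord(
                subject_id=str(row.subject_id),
                condition=Condition(row.condition),
                stimulus=Stimulus(row.stimulus),
                size_ratio=float(row.size_ratio),
                response=Response(resp) if resp not in ("", None) and resp == resp else None,
                confidence=int(conf) if conf not in ("", None) and conf == conf else None,
                is_filler=bool(row.is_filler),
            )
        )
    return trials


def write_trials(trials: Iterable[TrialRecord] | pd.DataFrame, path: str | Path) -> None:
    frame = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_trials(path: str | Path) -> list[TrialRecord]:
    frame = pd.read_csv(path, keep_default_na=False, dtype={"confidence": str})
    return frame_to_trials(frame)


def ratings_to_frame(sheets: Iterable[RatingSheet]) -> pd.DataFrame:
    items = trait_items()
    ids = dict(zip(items["word"], items["item_id"]))
    rows = []
    for sheet in sheets:
        for word, score in sheet.scores.items():
            rows.append(
                {
                    "subject_id": sheet.subject_id,
                    "item_id": ids.get(word, 0),  # 0 for fillers / unknown words
                    "word": word,
                    "item_class": ItemClass(sheet.classes[word]).value,
                    "raw_score": score,
                }
            )
    return pd.DataFrame(rows, columns=RATING_COLUMNS)


def write_ratings(sheets: Iterable[RatingSheet] | pd.DataFrame, path: str | Path) -> None:
    frame = sheets if isinstance(sheets, pd.DataFrame) else ratings_to_frame(sheets)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_ratings(path: str | Path) -> list[RatingSheet]:
    frame = pd.read_csv(path, keep_default_na=False)
    sheets = []
    for sid, group in frame.groupby("subject_id", sort=True):
        scores = dict(zip(group["word"], group["raw_score"].astype(float)))
        classes = {w: ItemClass(c) for w, c in zip(group["word"], group["item_class"])}
        sheets.append(RatingSheet(str(sid), scores, classes))
    return sheets
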