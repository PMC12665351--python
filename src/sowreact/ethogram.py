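"""Ethogram scoring for the sow shaving test.

During the standardized shaving test each lactating sow is observed
directly.  The observers record:

* the sow's **posture** at three time points (before any contact, after
  the first side is shaved, after the second side is shaved), coded on a
  four-level alertness scale from lying laterally (``LDL``, least alert)
  to standing (``STD``, most alert);
* the **vocalization types** produced at three or four stages of the
  procedure — short grunt (``SGT``), long grunt (``LGT``) and bark
  (``BRK``) — each stage observation being a subset of the three types;
* the **shave time** in seconds (trait ST), the number of touches applied
  by the shaver, the moment of any repositioning intervention, and a hair
  density score.

Three behavioral traits are derived per session:

* ``VS`` (vocalization score): each stage subset is mapped to an ordinal
  0–7 score and the stage scores are summed.
* posture-change scores: the signed ordinal difference between
  consecutive postures, in [-3, 3]; positive means increased alertness.
* ``RS`` (responsiveness score): the vocalization score combined
  additively with the two posture-change scores.
* ``ST`` (shave time): used as recorded, in seconds.

This module also computes the descriptive summary (mean, SD, CV, min,
max) per trait, applying a 3-SD outlier rule to continuous traits only.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MalformedSessionError

logger = logging.getLogger(__name__)

__all__ = [
    "Posture",
    "Vocalization",
    "EthogramSession",
    "posture_change_score",
    "vocalization_stage_score",
    "vocalization_score",
    "responsiveness_score",
    "score_session",
    "score_sessions",
    "trait_summary",
    "cv",
    "read_sessions_csv",
    "sessions_from_frame",
]


class Posture(enum.IntEnum):
    """Posture codes ordered from least alert to most alert."""

    LDL = 0  # lying down laterally
    LDS = 1  # lying down sternally
    SIT = 2  # sitting
    STD = 3  # standing


class Vocalization(enum.Enum):
    """Vocalization types distinguished by the ethogram."""

    SGT = "SGT"  # short grunt
    LGT = "LGT"  # long grunt
    BRK = "BRK"  # bark


#: Ordinal score of each possible stage observation (a subset of the
#: three vocalization types).  The scale runs from silence (0) to a pure
#: bark (7); mixtures are ranked between those extremes.
VOCAL_STAGE_SCORES: dict[frozenset, int] = {
    frozenset(): 0,
    frozenset({Vocalization.SGT}): 1,
    frozenset({Vocalization.SGT, Vocalization.LGT}): 2,
    frozenset({Vocalization.LGT}): 3,
    frozenset({Vocalization.SGT, Vocalization.LGT, Vocalization.BRK}): 4,
    frozenset({Vocalization.SGT, Vocalization.BRK}): 5,
    frozenset({Vocalization.LGT, Vocalization.BRK}): 6,
    frozenset({Vocalization.BRK}): 7,
}

#: Inverse lookup: stage score -> subset, used by the simulator.
STAGE_SCORE_TO_SUBSET: dict[int, frozenset] = {
    v: k for k, v in VOCAL_STAGE_SCORES.items()
}

INTERVENTION_MOMENTS = ("none", "between_sites", "before_first_site")


def _as_posture(code) -> Posture:
    if isinstance(code, Posture):
        return code
    try:
        return Posture[str(code).strip().upper()]
    except KeyError:
        raise MalformedSessionError(
            f"unknown posture code {code!r}; expected one of "
            f"{[p.name for p in Posture]}"
        ) from None


def _as_vocal_subset(observed) -> frozenset:
    out = set()
    for v in observed:
        if isinstance(v, Vocalization):
            out.add(v)
        else:
            try:
                out.add(Vocalization[str(v).strip().upper()])
            except KeyError:
                raise MalformedSessionError(
                    f"unknown vocalization type {v!r}; expected SGT/LGT/BRK"
                ) from None
    return frozenset(out)


def posture_change_score(prev, curr) -> int:
    """Signed ordinal posture change between two consecutive time points.

    The four postures are ordered levels (LDL=0 < LDS=1 < SIT=2 < STD=3)
    and the score is ``level(curr) - level(prev)``, in [-3, 3].  A
    positive score means the sow became more alert (e.g. LDS -> STD
    scores 2), a negative score that it settled down (STD -> LDS scores
    -2), and 0 that it did not change posture.
    """
    return int(_as_posture(curr)) - int(_as_posture(prev))


def vocalization_stage_score(observed: Iterable) -> int:
    """Ordinal 0-7 score of one stage's vocalization subset.

    All 8 subsets of {SGT, LGT, BRK} are mapped: silence scores 0, a pure
    bark scores 7, and mixed observations fall in between.
    """
    return VOCAL_STAGE_SCORES[_as_vocal_subset(observed)]


def vocalization_score(stage_vocalizations: Sequence[Iterable]) -> int:
    """Vocalization score VS: the sum of the per-stage scores.

    A session has 3 stages (no repositioning intervention) or 4 stages
    (stage 3 records the reaction to the intervention); anything else is
    a malformed session.
    """
    n = len(stage_vocalizations)
    if n not in (3, 4):
        raise MalformedSessionError(
            f"expected 3 or 4 vocalization stages, got {n}"
        )
    return sum(vocalization_stage_score(s) for s in stage_vocalizations)


def responsiveness_score(vs: int, posture_change_scores: Sequence[int]) -> int:
    """Responsiveness score RS combining vocal and postural reactivity.

    RS is the vocalization score plus the sum of the two posture-change
    scores (unclipped): standing up adds, settling down subtracts, and a
    silent sow that never moves scores exactly 0.
    """
    if vs < 0:
        raise MalformedSessionError(f"vs must be non-negative, got {vs}")
    pcs = list(posture_change_scores)
    if len(pcs) != 2:
        raise MalformedSessionError(
            f"expected 2 posture-change scores, got {len(pcs)}"
        )
    return int(vs) + int(sum(pcs))


@dataclass
class EthogramSession:
    """One sow's raw shaving-test observation record."""

    sow_id: str
    postures: Sequence  # exactly 3 codes: before contact, after side 1, after side 2
    stage_vocalizations: Sequence  # 3 or 4 subsets of {SGT, LGT, BRK}
    shave_time_s: float
    touches: int = 0
    intervention_moment: str = "none"
    hair_density: int = 1
    contemporary_group: str = "cg1"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.postures) != 3:
            raise MalformedSessionError(
                f"sow {self.sow_id}: expected 3 posture observations, "
                f"got {len(self.postures)}"
            )
        self.postures = [_as_posture(p) for p in self.postures]
        if len(self.stage_vocalizations) not in (3, 4):
            raise MalformedSessionError(
                f"sow {self.sow_id}: expected 3 or 4 vocalization stages, "
                f"got {len(self.stage_vocalizations)}"
            )
        self.stage_vocalizations = [
            _as_vocal_subset(s) for s in self.stage_vocalizations
        ]
        if not self.shave_time_s > 0:
            raise MalformedSessionError(
                f"sow {self.sow_id}: shave_time_s must be positive, "
                f"got {self.shave_time_s}"
            )
        if self.intervention_moment not in INTERVENTION_MOMENTS:
            raise MalformedSessionError(
                f"sow {self.sow_id}: unknown intervention moment "
                f"{self.intervention_moment!r}"
            )
        if self.touches < 0:
            raise MalformedSessionError(
                f"sow {self.sow_id}: touches must be non-negative"
            )


def score_session(session: EthogramSession) -> dict:
    """Score one session into the derived traits RS, VS and ST."""
    pcs = [
        posture_change_score(a, b)
        for a, b in zip(session.postures[:-1], session.postures[1:])
    ]
    vs = vocalization_score(session.stage_vocalizations)
    rs = responsiveness_score(vs, pcs)
    return {
        "sow_id": session.sow_id,
        "rs": rs,
        "vs": vs,
        "st": float(session.shave_time_s),
        "posture_change_1": pcs[0],
        "posture_change_2": pcs[1],
        "touches": session.touches,
        "intervention_moment": session.intervention_moment,
        "hair_density": session.hair_density,
        "contemporary_group": session.contemporary_group,
        "n_stages": len(session.stage_vocalizations),
    }


def cv(mean: float, sd: float) -> float:
    """Coefficient of variation SD/mean as a fraction."""
    if mean == 0:
        return float("nan")
    return sd / mean


def trait_summary(values: np.ndarray, trait: str, outlier_sd: float | None) -> dict:
    """Descriptive statistics for one trait, with optional 3-SD trimming.

    ``outlier_sd`` is applied to continuous traits only: records further
    than ``outlier_sd`` standard deviations from the mean are removed
    before the summary is computed.  With a single record the SD is
    undefined and flagged instead of trimmed.
    """
    x = np.asarray(values, dtype=float)
    n0 = x.size
    removed = 0
    if n0 == 0:
        return {"trait": trait, "n": 0, "removed": 0}
    if n0 == 1:
        return {
            "trait": trait,
            "n": 1,
            "removed": 0,
            "mean": float(x[0]),
            "sd": np.nan,
            "cv": np.nan,
            "min": float(x[0]),
            "median": float(x[0]),
            "max": float(x[0]),
            "sd_undefined": True,
        }
    if outlier_sd is not None:
        m, s = x.mean(), x.std(ddof=1)
        keep = np.abs(x - m) <= outlier_sd * s
        removed = int((~keep).sum())
        x = x[keep]
    m, s = x.mean(), x.std(ddof=1)
    return {
        "trait": trait,
        "n": int(x.size),
        "removed": removed,
        "mean": float(m),
        "sd": float(s),
        "cv": float(cv(m, s)),
        "min": float(x.min()),
        "median": float(np.median(x)),
        "max": float(x.max()),
        "sd_undefined": False,
    }


def score_sessions(
    sessions: Iterable[EthogramSession],
    outlier_sd: float | None = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a batch of sessions and summarize the derived traits.

    Returns ``(scores, summary)``: one scored row per retained session
    and a descriptive-statistics table (mean, SD, CV, min, median, max
    per trait).  The outlier rule (records beyond ``outlier_sd`` SDs of
    the trait mean removed before summarizing) applies to the continuous
    trait ST only; the categorical scores RS and VS keep every record.
    Sessions that fail the session invariants are dropped with a logged
    reason.
    """
    rows = []
    for s in sessions:
        try:
            rows.append(score_session(s))
        except MalformedSessionError as exc:
            logger.warning("dropping session: %s", exc)
    if not rows:
        logger.warning("no scoreable sessions; returning empty tables")
        return pd.DataFrame(), pd.DataFrame()
    scores = pd.DataFrame(rows)

    summaries = [
        trait_summary(scores["rs"].to_numpy(), "RS", None),
        trait_summary(scores["vs"].to_numpy(), "VS", None),
        trait_summary(scores["st"].to_numpy(), "ST", outlier_sd),
    ]
    summary = pd.DataFrame(summaries)

    # drop ST outlier records from the scored table as well, so the
    # downstream model sees the same records the summary describes
    if outlier_sd is not None and len(scores) > 1:
        st = scores["st"]
        m, s = st.mean(), st.std(ddof=1)
        keep = (st - m).abs() <= outlier_sd * s
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("removed %d ST outlier record(s) beyond %.1f SD",
                        n_drop, outlier_sd)
        scores = scores.loc[keep].reset_index(drop=True)
    return scores, summary


# ---------------------------------------------------------------------------
# delimited-text interface
#
# One row per sow-session.  Postures use the ethogram abbreviations
# (posture_1..posture_3); vocalization stages are semicolon-separated
# lists of SGT/LGT/BRK (voc_stage_1..voc_stage_4), with "NONE" (or an
# empty list) meaning silence and a missing value meaning the stage did
# not occur (3-stage session).


def _parse_stage(cell) -> frozenset | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip()
    if text == "" or text.upper() in ("NA", "ABSENT"):
        return None
    if text.upper() == "NONE":
        return frozenset()
    return _as_vocal_subset(t for t in text.split(";") if t.strip())


def sessions_from_frame(df: pd.DataFrame) -> list[EthogramSession]:
    """Build sessions from a table; rows violating invariants are dropped."""
    sessions = []
    for _, row in df.iterrows():
        stages = []
        for k in range(1, 5):
            col = f"voc_stage_{k}"
            if col in row.index:
                sub = _parse_stage(row[col])
                if sub is not None:
                    stages.append(sub)
        try:
            postures = [row[f"posture_{k}"] for k in range(1, 4)]
            if any(pd.isna(p) for p in postures):
                raise MalformedSessionError(
                    f"sow {row.get('sow_id')}: missing posture observation"
                )
            sessions.append(
                EthogramSession(
                    sow_id=str(row["sow_id"]),
                    postures=postures,
                    stage_vocalizations=stages,
                    shave_time_s=float(row["shave_time_s"]),
                    touches=int(row.get("touches", 0)),
                    intervention_moment=str(row.get("intervention_moment", "none")),
                    hair_density=int(row.get("hair_density", 1)),
                    contemporary_group=str(row.get("contemporary_group", "cg1")),
                )
            )
        except (MalformedSessionError, KeyError, ValueError) as exc:
            logger.warning("dropping row: %s", exc)
    return sessions


def read_sessions_csv(path) -> list[EthogramSession]:
    """Read session records from a delimited text file (CSV/TSV)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return sessions_from_frame(pd.read_csv(path, sep=sep))
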