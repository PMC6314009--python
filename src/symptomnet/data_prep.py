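"""Sample selection, item dichotomization, matrix preparation and reliability.

The entry points mirror the preprocessing applied to a cohort of simultaneous
alcohol-and-cannabis users before network estimation:

* :func:`select_simultaneous_users` — keep respondents endorsing simultaneous
  use at least "hardly ever" on a six-point frequency scale;
* :func:`dichotomize_cudit` — recode ordinal CUDIT answers to presence/absence;
* :func:`prepare_matrix` — listwise-delete missing rows and drop zero-variance
  columns, producing a :class:`SymptomData` plus a preparation log;
* :func:`reliability` — KR-20 and Spearman–Brown split-half reliability.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "SIMULTANEOUS_USE_SCALE",
    "RawResponses",
    "CUDIT_SCALES",
    "SymptomData",
    "ReliabilityReport",
    "select_simultaneous_users",
    "dichotomize_cudit",
    "prepare_matrix",
    "reliability",
    "spearman_brown",
    "infer_cluster_labels",
]

#: Six-point frequency scale of the simultaneous-use screening item, ordered
#: from the lowest to the highest frequency.
SIMULTANEOUS_USE_SCALE = (
    "never",
    "hardly ever",
    "seldom",
    "more or less half of the time",
    "often",
    "almost always",
)

#: Ordinal answer scales per CUDIT item (1-based ids). Items 1 and 2 have
#: their own frequency/duration scales without a "never" option (the scale is
#: only administered to users); items 3-10 share a five-point frequency scale.
CUDIT_SCALES: Mapping[int, tuple[str, ...]] = {
    1: ("less than a month", "monthly", "weekly", "daily or almost daily"),
    2: ("one or two h", "three or four h", "five or six h", "seven h or more"),
    **{
        i: ("never", "less than monthly", "monthly", "weekly", "daily or almost daily")
        for i in range(3, 11)
    },
}

_MISSING_STRINGS = {"", "na", "nan", "none"}


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str) and value.strip().lower() in _MISSING_STRINGS:
        return True
    return False


@dataclasses.dataclass
class RawResponses:
    """Raw survey responses before screening and dichotomization.

    ``simultaneous_use_answer`` holds one six-point frequency category per
    respondent; ``cudit_items`` the ordinal CUDIT answers (columns keyed by
    item id 1..10); ``aud_items`` the already-binary DSM-5 alcohol items.
    Missing markers are allowed anywhere.
    """

    simultaneous_use_answer: Sequence
    cudit_items: pd.DataFrame
    aud_items: pd.DataFrame

    def to_binary_frame(self) -> pd.DataFrame:
        """Dichotomized A1..A11 / C1..C10 table for the screened-in rows.

        Rows failing the simultaneous-use screen are dropped; missing item
        answers stay missing (NaN) for downstream listwise deletion.
        """
        mask = select_simultaneous_users(self.simultaneous_use_answer)
        aud = self.aud_items.loc[mask].reset_index(drop=True)
        aud.columns = [f"A{i + 1}" for i in range(aud.shape[1])]
        cudit = {}
        for k, column in enumerate(self.cudit_items.columns, start=1):
            raw = self.cudit_items.loc[mask, column].reset_index(drop=True)
            cudit[f"C{k}"] = raw.map(
                lambda v: np.nan if _is_missing(v) else dichotomize_cudit(k, v)
            )
        return pd.concat([aud, pd.DataFrame(cudit)], axis=1)


def select_simultaneous_users(answers) -> np.ndarray:
    """Boolean mask of respondents who report simultaneous use.

    A respondent is included iff the screening answer is "hardly ever" or any
    higher frequency category. Missing answers exclude the respondent.
    Accepts a sequence of answers or a :class:`RawResponses`.

    Raises
    ------
    DataError
        If an answer is not on the six-point scale (the offending value is
        named in the message).
    """
    if isinstance(answers, RawResponses):
        answers = answers.simultaneous_use_answer
    include_from = SIMULTANEOUS_USE_SCALE.index("hardly ever")
    mask = np.zeros(len(answers), dtype=bool)
    for idx, answer in enumerate(answers):
        if _is_missing(answer):
            continue
        key = str(answer).strip().lower()
        if key not in SIMULTANEOUS_USE_SCALE:
            raise DataError(
                f"unknown simultaneous-use category {answer!r} at position {idx}; "
                f"expected one of {SIMULTANEOUS_USE_SCALE}"
            )
        mask[idx] = SIMULTANEOUS_USE_SCALE.index(key) >= include_from
    return mask


def dichotomize_cudit(item_id: int, ordinal_answer: str) -> int:
    """Recode one ordinal CUDIT answer to 0 (absence) / 1 (presence).

    Items 3-10: "never" maps to 0, any more frequent category to 1. Items 1
    and 2 lack a "never" option; only their single lowest category maps to 0.
    """
    if item_id not in CUDIT_SCALES:
        raise DataError(f"CUDIT item id must be in 1..10, got {item_id!r}")
    scale = CUDIT_SCALES[item_id]
    key = str(ordinal_answer).strip().lower()
    if key not in scale:
        raise DataError(
            f"answer {ordinal_answer!r} is not on the scale of CUDIT item "
            f"{item_id}; expected one of {scale}"
        )
    return 0 if scale.index(key) == 0 else 1


def infer_cluster_labels(symptom_labels: Sequence[str]) -> list[str]:
    """Map symptom labels to disorder clusters by their leading letter.

    ``A*`` labels are alcohol items, ``C*`` labels cannabis items.
    """
    clusters = []
    for label in symptom_labels:
        head = label.strip()[:1].upper()
        if head == "A":
            clusters.append("alcohol")
        elif head == "C":
            clusters.append("cannabis")
        else:
            raise DataError(
                f"cannot infer disorder cluster for symptom label {label!r}; "
                "provide cluster_labels explicitly"
            )
    return clusters


@dataclasses.dataclass
class SymptomData:
    """Prepared binary respondent-by-symptom matrix.

    Attributes
    ----------
    matrix : (n, p) int8 array with entries in {0, 1}, no missing values.
    symptom_labels : unique symptom identifiers, one per column.
    cluster_labels : disorder membership per column (e.g. alcohol/cannabis).
    """

    matrix: np.ndarray
    symptom_labels: list[str]
    cluster_labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.symptom_labels = [str(s) for s in self.symptom_labels]
        self.cluster_labels = [str(s) for s in self.cluster_labels]
        if self.matrix.ndim != 2:
            raise DataError("matrix must be two-dimensional")
        n, p = self.matrix.shape
        if len(self.symptom_labels) != p or len(self.cluster_labels) != p:
            raise DataError("label lengths must match the number of columns")
        if len(set(self.symptom_labels)) != p:
            raise DataError("symptom labels must be unique")
        vals = np.unique(self.matrix)
        if not np.all(np.isin(vals, [0, 1])):
            raise DataError("matrix entries must be 0/1 with no missing values")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def endorsement_rates(self) -> np.ndarray:
        """Column means (proportion of respondents endorsing each symptom)."""
        return self.matrix.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.symptom_labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cluster_labels: Sequence[str] | None = None) -> "SymptomData":
        labels = [str(c) for c in frame.columns]
        clusters = list(cluster_labels) if cluster_labels is not None else infer_cluster_labels(labels)
        return cls(frame.to_numpy(), labels, clusters)


def read_symptom_csv(path) -> pd.DataFrame:
    """Read a respondent-by-symptom CSV (header row of labels, UTF-8).

    Empty cells and "NA" are recognized as missing; values otherwise must be
    0/1 and are returned as floats with NaN for missing entries.
    """
    frame = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    return frame


def prepare_matrix(
    frame: pd.DataFrame | np.ndarray,
    cluster_labels: Sequence[str] | None = None,
    min_rows: int = 50,
) -> tuple[SymptomData, dict]:
    """Listwise-delete missing rows and drop zero-variance columns.

    Parameters
    ----------
    frame
        Respondent-by-symptom table with entries in {0, 1, missing}. A bare
        array is accepted and given labels ``X1..Xp`` (clusters then required).
    cluster_labels
        Disorder membership per column; inferred from A*/C* labels if omitted.
    min_rows
        Minimum number of retained respondents.

    Returns
    -------
    (SymptomData, log)
        The prepared data and a JSON-serializable preparation log with the
        dropped-row count, dropped columns with reasons, and the endorsement
        rate of every retained column.
    """
    if isinstance(frame, np.ndarray):
        frame = pd.DataFrame(frame, columns=[f"X{i + 1}" for i in range(frame.shape[1])])
    labels = [str(c) for c in frame.columns]
    if cluster_labels is None:
        clusters = infer_cluster_labels(labels)
    else:
        if len(cluster_labels) != len(labels):
            raise DataError("cluster_labels length must match the number of columns")
        clusters = [str(c) for c in cluster_labels]

    values = frame.to_numpy(dtype=float)
    finite = np.isfinite(values)
    bad = finite & ~np.isin(values, [0.0, 1.0])
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise DataError(
            f"entry at row {r}, column {labels[c]!r} is {values[r, c]!r}; "
            "expected 0, 1 or missing"
        )

    complete = finite.all(axis=1)
    n_dropped_rows = int((~complete).sum())
    kept = values[complete]

    dropped_columns = []
    keep_cols = []
    for j, label in enumerate(labels):
        col = kept[:, j] if kept.size else np.empty(0)
        if kept.shape[0] > 0 and np.all(col == col[0]):
            reason = (
                "no variance (symptom endorsed by all retained respondents)"
                if col[0] == 1.0
                else "no variance (symptom endorsed by no retained respondent)"
            )
            dropped_columns.append({"label": label, "reason": reason})
        else:
            keep_cols.append(j)

    if len(keep_cols) < 2:
        raise DataError(
            f"fewer than 2 columns with variance remain ({len(keep_cols)}); "
            "network preparation failed"
        )
    if kept.shape[0] < min_rows:
        raise DataError(
            f"only {kept.shape[0]} complete rows remain, below the minimum of {min_rows}"
        )

    data = SymptomData(
        kept[:, keep_cols].astype(np.int8),
        [labels[j] for j in keep_cols],
        [clusters[j] for j in keep_cols],
    )
    log = {
        "n_input_rows": int(values.shape[0]),
        "n_dropped_rows": n_dropped_rows,
        "n_retained_rows": int(data.n),
        "dropped_columns": dropped_columns,
        "endorsement_rates": {
            label: float(rate)
            for label, rate in zip(data.symptom_labels, data.endorsement_rates())
        },
    }
    return data, log


def write_preparation_log(log: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(log, handle, indent=2)


def spearman_brown(r: float) -> float:
    """Spearman–Brown step-up correction of a half-test correlation."""
    return 2.0 * r / (1.0 + r)


@dataclasses.dataclass(frozen=True)
class ReliabilityReport:
    """Internal-consistency summary of a dichotomous scale."""

    kr20: float
    split_half: float
    half_correlation: float
    item_props: np.ndarray
    total_score_variance: float
    split: tuple[tuple[int, ...], tuple[int, ...]]


def reliability(data: SymptomData | np.ndarray, split_seed: int = 0) -> ReliabilityReport:
    """KR-20 and Spearman–Brown-corrected split-half reliability.

    KR-20 = K/(K-1) * (1 - sum(p_i q_i) / sigma^2), with population (ddof=0)
    variances throughout. The split halves are a seeded random partition of
    the items into two sets of (near-)equal size; the Pearson correlation of
    the two half scores is stepped up with the Spearman–Brown formula.
    """
    matrix = data.matrix if isinstance(data, SymptomData) else np.asarray(data)
    n, k = matrix.shape
    if k < 2 or n < 2:
        raise DataError("reliability requires at least 2 items and 2 respondents")
    props = matrix.mean(axis=0)
    item_var = props * (1.0 - props)
    total = matrix.sum(axis=1)
    sigma2 = float(np.var(total, ddof=0))
    if sigma2 == 0.0:
        raise DataError("total-score variance is zero; reliability undefined")
    kr20 = (k / (k - 1.0)) * (1.0 - item_var.sum() / sigma2)

    rng = np.random.default_rng(split_seed)
    order = rng.permutation(k)
    cut = (k + 1) // 2
    first, second = np.sort(order[:cut]), np.sort(order[cut:])
    half_a = matrix[:, first].sum(axis=1).astype(float)
    half_b = matrix[:, second].sum(axis=1).astype(float)
    if np.var(half_a) == 0.0 or np.var(half_b) == 0.0:
        raise DataError("a split half has zero variance; split-half reliability undefined")
    r = float(np.corrcoef(half_a, half_b)[0, 1])
    return ReliabilityReport(
        kr20=float(kr20),
        split_half=spearman_brown(r),
        half_correlation=r,
        item_props=props,
        total_score_variance=sigma2,
        split=(tuple(int(i) for i in first), tuple(int(i) for i in second)),
    )
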