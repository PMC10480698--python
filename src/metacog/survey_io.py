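"""Reading, validating and recoding truth-judgement survey data.

The survey instrument shows each respondent a set of statements (split between
two knowledge domains, half true and half false) and collects a single 6-point
response that combines the truth judgement with graded confidence:

    1  "extremely confident ... true"
    2  "fairly confident ... true"
    3  "think true, not at all confident"
    4  "think false, not at all confident"
    5  "fairly confident ... false"
    6  "extremely confident ... false"

This module turns long-format CSV records into the sufficient statistic for
all signal-detection fitting — one 2 (stimulus) x 2 (judgement) x 3
(confidence) count table per respondent x domain — plus the robustness filter
that drops respondents endorsing a flagged conspiracy statement, and a
Cronbach's alpha summary of item internal consistency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DOMAINS",
    "TRUTHS",
    "ResponseTable",
    "ConfidenceCounts",
    "AttitudeTable",
    "recode_response",
    "decode_response",
    "read_responses",
    "tabulate_counts",
    "filter_conspiracy_believers",
    "cronbach_alpha",
]

DOMAINS = ("science", "covid")
TRUTHS = ("true_statement", "false_statement")

REQUIRED_COLUMNS = ("respondent_id", "statement_id", "domain", "truth", "raw_response")

# raw 6-point value -> (judgement, confidence); judgement 0 = respond_true
_RECODE = {
    1: (0, 3), 2: (0, 2), 3: (0, 1),
    4: (1, 1), 5: (1, 2), 6: (1, 3),
}
_DECODE = {v: k for k, v in _RECODE.items()}


def recode_response(raw: int) -> tuple[str, int]:
    """Map a raw 6-point response to (judgement, confidence 1-3)."""
    if raw not in _RECODE:
        raise ValueError(f"raw_response must be in 1..6, got {raw!r}")
    j, conf = _RECODE[raw]
    return ("respond_true" if j == 0 else "respond_false", conf)


def decode_response(judgement: str, confidence: int) -> int:
    """Inverse of :func:`recode_response`."""
    j = {"respond_true": 0, "respond_false": 1}[judgement]
    return _DECODE[(j, int(confidence))]


class SchemaError(ValueError):
    pass


class IntegrityError(ValueError):
    pass


@dataclass
class ResponseTable:
    """Validated long-format truth-judgement records.

    ``df`` carries one row per respondent x statement with canonical columns
    plus the derived ``judgement`` (0 = respond true) and ``confidence`` (1-3).
    ``rejected`` holds input rows dropped at validation; ``log`` accumulates a
    JSON-serialisable record of every filter applied.
    """

    df: pd.DataFrame
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)
    log: list = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = self.df.copy()
        bad_domain = ~df["domain"].isin(DOMAINS)
        bad_truth = ~df["truth"].isin(TRUTHS)
        if bad_domain.any() or bad_truth.any():
            raise SchemaError("domain/truth values outside the declared enums")
        dup = df.duplicated(subset=["respondent_id", "statement_id"])
        if dup.any():
            raise IntegrityError(
                f"{int(dup.sum())} duplicate (respondent_id, statement_id) pairs"
            )
        coded = df["raw_response"].map(lambda r: _RECODE.get(r))
        df["judgement"] = [jc[0] if jc else -1 for jc in coded]
        df["confidence"] = [jc[1] if jc else -1 for jc in coded]
        self.df = df

    @property
    def respondents(self) -> np.ndarray:
        return self.df["respondent_id"].unique()

    def write_log(self, path) -> None:
        Path(path).write_text(json.dumps(self.log, indent=2, default=str))


@dataclass(frozen=True)
class ConfidenceCounts:
    """Stimulus x judgement x confidence counts for one respondent x domain."""

    counts: np.ndarray  # shape (2, 2, 3), ints
    n_total: int

    def type1_table(self) -> np.ndarray:
        """Collapse over confidence to the 2x2 type-1 table."""
        return self.counts.sum(axis=2)


def read_responses(path, schema: dict | None = None) -> ResponseTable:
    """Read a long-format response CSV into a validated :class:`ResponseTable`.

    ``schema`` adapts foreign headers and codings:
    ``{"columns": {canonical: file_header, ...},
    "domain_values": {file_value: "science"|"covid"},
    "truth_values": {file_value: "true_statement"|"false_statement"}}``.
    Rows with an out-of-range raw response are rejected and reported on the
    returned table rather than raising.
    """
    df = pd.read_csv(path)
    schema = schema or {}
    colmap = schema.get("columns", {})
    rename = {v: k for k, v in colmap.items()}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for key, target in (("domain_values", "domain"), ("truth_values", "truth")):
        if key in schema:
            df[target] = df[target].map(schema[key])
    df["raw_response"] = pd.to_numeric(df["raw_response"], errors="coerce")
    ok = df["raw_response"].isin(list(_RECODE))
    rejected = df.loc[~ok]
    df = df.loc[ok].copy()
    df["raw_response"] = df["raw_response"].astype(int)
    table = ResponseTable(df=df, rejected=rejected)
    table.log.append({
        "op": "read_responses", "path": str(path),
        "rows": int(len(df)), "rejected": int(len(rejected)),
        "respondents": int(df["respondent_id"].nunique()),
    })
    return table


def tabulate_counts(table: ResponseTable) -> dict[tuple, ConfidenceCounts]:
    """One :class:`ConfidenceCounts` per (respondent, domain); totals conserved."""
    out: dict[tuple, ConfidenceCounts] = {}
    stim_idx = {"true_statement": 0, "false_statement": 1}
    df = table.df
    for (rid, domain), grp in df.groupby(["respondent_id", "domain"], sort=True):
        counts = np.zeros((2, 2, 3), dtype=int)
        np.add.at(
            counts,
            (
                grp["truth"].map(stim_idx).to_numpy(),
                grp["judgement"].to_numpy(),
                grp["confidence"].to_numpy() - 1,
            ),
            1,
        )
        out[(rid, domain)] = ConfidenceCounts(counts=counts, n_total=len(grp))
    return out


def filter_conspiracy_believers(
    table: ResponseTable, statement_id
) -> tuple[ResponseTable, float]:
    """Drop respondents who judged the flagged conspiracy statement true.

    A respondent is excluded when their raw response to ``statement_id`` is in
    {1, 2, 3} (any confidence level of "true").  Returns the filtered table and
    the excluded fraction of respondents.  Idempotent.
    """
    df = table.df
    rows = df[df["statement_id"] == statement_id]
    if rows.empty:
        raise LookupError(f"statement {statement_id!r} not present in table")
    believers = set(rows.loc[rows["judgement"] == 0, "respondent_id"])
    n_resp = df["respondent_id"].nunique()
    fraction = len(believers) / n_resp
    kept = df[~df["respondent_id"].isin(believers)].copy()
    out = ResponseTable(df=kept, rejected=table.rejected, log=list(table.log))
    out.log.append({
        "op": "filter_conspiracy_believers", "statement_id": statement_id,
        "excluded_respondents": len(believers), "excluded_fraction": fraction,
    })
    return out, fraction


def correctness_matrix(table: ResponseTable, domain: str) -> pd.DataFrame:
    """Respondent x statement binary correctness (judgement matches label)."""
    df = table.df[table.df["domain"] == domain].copy()
    truth_j = df["truth"].map({"true_statement": 0, "false_statement": 1})
    df["correct"] = (df["judgement"] == truth_j).astype(int)
    return df.pivot(index="respondent_id", columns="statement_id", values="correct")


def cronbach_alpha(table: ResponseTable, domain: str) -> float:
    """Cronbach's alpha over the item-correctness columns of one domain.

    alpha = K/(K-1) * (1 - sum_i var_i / var_total), computed on respondents
    with complete item sets.  Confidence is ignored: correctness is binary.
    """
    mat = correctness_matrix(table, domain).dropna(axis=0)
    k = mat.shape[1]
    if k < 2:
        raise ValueError("need at least 2 items for Cronbach's alpha")
    item_vars = mat.var(axis=0, ddof=1)
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroDivisionError("zero total variance: alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass
class AttitudeTable:
    """Per-respondent ordinal outcomes and covariates.

    ``outcomes`` maps each outcome column to its ordered category list;
    ``group_vars`` are categorical covariates used as random intercepts, each
    carrying an explicit ``"missing"`` level wherever a value is absent.
    """

    df: pd.DataFrame
    outcomes: dict[str, list]
    group_vars: list[str] = field(default_factory=list)

    def __post_init__(self):
        df = self.df.copy()
        for col, cats in self.outcomes.items():
            if col not in df.columns:
                raise SchemaError(f"outcome column {col!r} missing")
            extra = set(df[col].dropna()) - set(cats)
            if extra:
                raise SchemaError(f"outcome {col!r} has undeclared categories {extra}")
        for col in self.group_vars:
            vals = df[col].astype(object)
            vals = vals.where(~vals.isna(), "missing")
            df[col] = vals.astype(str)
        self.df = df


def write_counts_csv(counts: dict[tuple, ConfidenceCounts], path) -> None:
    """Tidy per-respondent counts: one row per cell with nonnegative count."""
    rows = []
    for (rid, domain), cc in counts.items():
        for s, stim in enumerate(TRUTHS):
            for j, judge in enumerate(("respond_true", "respond_false")):
                for conf in range(3):
                    rows.append({
                        "respondent_id": rid, "domain": domain, "stimulus": stim,
                        "judgement": judge, "confidence": conf + 1,
                        "count": int(cc.counts[s, j, conf]),
                    })
    pd.DataFrame(rows).to_csv(path, index=False)
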