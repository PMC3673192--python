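"""Chemical-disease inference scores and their availability pattern.

An inference score Y quantifies curated-network support for a link between a
metal ion (chemical C) and a cardiovascular endpoint (disease D) through
shared genes G: Y = -ln[P(G associated with both C and D | k, n_G) * P(no
other G connects C and D | k, n_G)].  The two probabilities come from the
curating database's scale-free network model and are treated as given
inputs; this module only composes them, stores score tables, and applies the
natural-log transform used throughout the regressions (scores must therefore
be strictly positive).

Missing (endpoint, ion) pairs are structural — a pair the database has no
evidence for simply has no score — and are never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ion_properties import assign_group

#: The five cardiovascular endpoints screened.
ENDPOINTS: tuple[str, ...] = (
    "cardiac arrhythmia",
    "myocardial infarction",
    "myocardial ischemia",
    "stroke",
    "thrombosis",
)


@dataclass(frozen=True)
class NetworkEvidence:
    """The two network probabilities behind one inference score.

    p_shared: P(a gene is associated with both chemical and disease | k, n_G)
    p_unique: P(no other gene connects them | k, n_G)
    k: gene-chemical/disease connection count; n_G: number of genes.
    """

    p_shared: float
    p_unique: float
    k: int = 0
    n_genes: int = 1

    def __post_init__(self) -> None:
        for name, p in (("p_shared", self.p_shared), ("p_unique", self.p_unique)):
            if not (0.0 < p <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {p}")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def compose_inference_score(evidence: NetworkEvidence | None = None,
                            p_shared: float | None = None,
                            p_unique: float | None = None) -> float:
    """Y = -ln(p_shared * p_unique), accepting either an evidence record or
    the two probabilities directly.  Symmetric in the two probabilities,
    non-negative, and zero iff both are 1."""
    if evidence is not None:
        p_shared, p_unique = evidence.p_shared, evidence.p_unique
    if p_shared is None or p_unique is None:
        raise TypeError("provide a NetworkEvidence or both probabilities")
    for p in (p_shared, p_unique):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"probability must lie in (0, 1], got {p}")
    return -(math.log(p_shared) + math.log(p_unique))


class DiseaseScoreSet:
    """Long-format (endpoint, ion) -> inference score container.

    Scores are strictly positive.  Endpoints beyond the five studied are
    retained but flagged non-core.  Availability (which ions have a score for
    an endpoint) is first-class and queryable per periodic-block group.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"endpoint", "ion", "inference_score"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"score table missing columns: {sorted(missing)}")
        df = frame.copy().reset_index(drop=True)
        if df["endpoint"].isna().any() or (df["endpoint"].astype(str).str.strip() == "").any():
            raise ValueError("empty endpoint value in score table")
        scores = pd.to_numeric(df["inference_score"], errors="coerce")
        if scores.isna().any():
            row = df.loc[scores.isna()].iloc[0]
            raise ValueError(f"non-numeric score for ({row['endpoint']}, {row['ion']})")
        if (scores <= 0).any():
            row = df.loc[scores <= 0].iloc[0]
            raise ValueError(
                f"inference score must be > 0 (log transform), got "
                f"{row['inference_score']} for ({row['endpoint']}, {row['ion']})"
            )
        df["inference_score"] = scores.astype(float)
        dup = df.duplicated(subset=["endpoint", "ion"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise ValueError(f"duplicate (endpoint, ion) pair: ({row['endpoint']}, {row['ion']})")
        df["core"] = df["endpoint"].isin(ENDPOINTS)
        self._df = df

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def endpoints(self) -> list[str]:
        return list(dict.fromkeys(self._df["endpoint"]))

    def ions_for(self, endpoint: str, group: str | None = None) -> list[str]:
        sub = self._df[self._df["endpoint"] == endpoint]
        ions = list(sub["ion"])
        if group is not None:
            ions = [i for i in ions if assign_group(i) == group]
        return ions

    def availability(self, endpoint: str, group: str | None = None) -> int:
        """Number of ions with a score for *endpoint* (optionally per group)."""
        return len(self.ions_for(endpoint, group))

    def score(self, endpoint: str, ion: str) -> float:
        sub = self._df[(self._df["endpoint"] == endpoint) & (self._df["ion"] == ion)]
        if sub.empty:
            raise KeyError(f"no score for ({endpoint}, {ion})")
        return float(sub["inference_score"].iloc[0])

    def to_csv(self, path) -> None:
        cols = [c for c in ("endpoint", "ion", "charge", "inference_score") if c in self._df]
        self._df[cols].to_csv(path, index=False)


def load_scores(path) -> DiseaseScoreSet:
    """Read a delimited (endpoint, ion, [charge,] inference_score) table."""
    import csv as _csv
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, _csv.Error):
        raise ValueError("score file is empty or unreadable") from None
    return DiseaseScoreSet(df)


def log_scores(scores: DiseaseScoreSet, endpoint: str, group: str) -> pd.Series:
    """Natural-log scores for one (endpoint, group) cell, indexed by ion.

    Ions without a score are simply absent from the result (structural
    missingness); an empty cell raises.
    """
    ions = scores.ions_for(endpoint, group)
    if not ions:
        raise ValueError(f"no ions available for ({endpoint}, {group})")
    vals = {ion: math.log(scores.score(endpoint, ion)) for ion in ions}
    return pd.Series(vals, name="ln_score", dtype=float)


def tidy_log_scores(scores: DiseaseScoreSet) -> pd.DataFrame:
    """Long-format (endpoint, group, ion, ln_score) frame for export."""
    rows = []
    for endpoint in scores.endpoints:
        for group in ("s-block", "transition"):
            try:
                series = log_scores(scores, endpoint, group)
            except ValueError:
                continue
            for ion, value in series.items():
                rows.append((endpoint, group, ion, value))
    return pd.DataFrame(rows, columns=["endpoint", "group", "ion", "ln_score"])
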