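"""Relative taxonomic bleaching susceptibility (BS) per survey.

Each surveyed taxon carries a susceptibility rank S_t from 1 (least) to 5
(most susceptible).  The survey-level score is the cover-weighted mean of
ranks divided by the total live coral cover:

    BS = (sum_t P_st * S_t) / P_s

where P_st is the percent-of-substrate cover of taxon t and P_s the total
live coral cover of survey s.  Unscored live cover (P_s > sum_t P_st)
deliberately dilutes BS toward 0, exactly as the formula implies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_SURVEYS_PER_TAXON = 6  # per-island reporting cutoff


class UnresolvableTaxonError(KeyError):
    """A surveyed taxon has no susceptibility score, even via genus fallback."""


@dataclass
class SusceptibilityTable:
    """Taxon code -> susceptibility score in {1..5}, with genus fallback.

    ``genus_of`` maps species-level codes to genus-level codes so a species
    missing from the score table can inherit its genus score (mirroring
    score tables published at both species and genus rank).
    """

    scores: "dict[str, float]"
    genus_of: "dict[str, str]" = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.genus_of is None:
            self.genus_of = {}
        bad = {t: s for t, s in self.scores.items() if not (1 <= s <= 5)}
        if bad:
            raise ValueError(f"susceptibility scores outside [1, 5]: {bad}")

    def resolve(self, taxon: str) -> float:
        if taxon in self.scores:
            return float(self.scores[taxon])
        genus = self.genus_of.get(taxon)
        if genus is not None and genus in self.scores:
            logger.info("taxon %s scored via genus fallback %s", taxon, genus)
            return float(self.scores[genus])
        raise UnresolvableTaxonError(taxon)

    @classmethod
    def from_csv(cls, path) -> "SusceptibilityTable":
        frame = pd.read_csv(path)
        genus_of = {}
        if "genus" in frame.columns:
            genus_of = {
                str(r.taxon): str(r.genus)
                for r in frame.itertuples()
                if isinstance(r.genus, str) and r.genus
            }
        return cls(
            scores=dict(zip(frame["taxon"].astype(str), frame["score"].astype(float))),
            genus_of=genus_of,
        )


@dataclass
class SurveyScore:
    survey_id: str
    total_cover: float  # P_s, % of substrate
    n_taxa: int
    bs: float


def compute_bs(
    rows: pd.DataFrame,
    table: SusceptibilityTable,
    total_cover: float,
    survey_id: str = "",
) -> SurveyScore:
    """BS = (sum_t P_st * S_t) / P_s for one survey.

    ``rows`` needs columns ``taxon`` and ``cover`` (percent of substrate).
    A survey with zero live cover has no defined score and raises
    ``ValueError``; callers exclude such surveys with a logged reason.
    """
    if total_cover <= 0:
        raise ValueError(f"survey {survey_id!r}: BS undefined for total cover {total_cover}")
    covers = rows["cover"].to_numpy(dtype=float)
    if (covers < 0).any():
        raise ValueError(f"survey {survey_id!r}: negative taxon cover")
    scores = np.array([table.resolve(t) for t in rows["taxon"]])
    bs = float(np.dot(covers, scores) / total_cover)
    # full precision internally; BS is rounded to 3 decimals at report time
    return SurveyScore(
        survey_id=survey_id,
        total_cover=float(total_cover),
        n_taxa=int(len(rows)),
        bs=bs,
    )


def resolve_synonyms(synonyms: "dict[str, str]") -> "dict[str, str]":
    """Transitive closure of a synonym map; rejects cycles.

    A chain A->B, B->C resolves A to C.
    """
    resolved: dict[str, str] = {}
    for start in synonyms:
        seen = {start}
        node = start
        while node in synonyms:
            node = synonyms[node]
            if node in seen:
                raise ValueError(f"cycle in synonym map involving {node!r}")
            seen.add(node)
        resolved[start] = node
    return resolved


def apply_synonyms(rows: pd.DataFrame, synonyms: "dict[str, str]") -> pd.DataFrame:
    """Rewrite taxon codes through a synonym map and merge duplicates per survey.

    Covers of merged taxa are summed within a survey; percent-bleached values
    merge as the cover-weighted mean so the bleached area is conserved.
    """
    if not synonyms:
        return rows.copy()
    closure = resolve_synonyms(synonyms)
    out = rows.copy()
    out["taxon"] = out["taxon"].map(lambda t: closure.get(t, t))
    keys = [c for c in ("survey_id", "island") if c in out.columns] + ["taxon"]

    def _merge(g: pd.DataFrame) -> pd.Series:
        total = g["cover"].sum()
        merged = {"cover": total}
        if "taxon_pct_bleached" in g.columns:
            if total > 0:
                merged["taxon_pct_bleached"] = float(
                    np.average(g["taxon_pct_bleached"], weights=g["cover"])
                )
            else:
                merged["taxon_pct_bleached"] = float(g["taxon_pct_bleached"].mean())
        for c in g.columns:
            if c not in merged and c not in keys:
                merged[c] = g[c].iloc[0]
        return pd.Series(merged)

    merged = out.groupby(keys, sort=False, as_index=False).apply(_merge, include_groups=False)
    return merged.reset_index(drop=True)[[*keys, *[c for c in out.columns if c not in keys]]]


def taxon_bleaching_summary(
    rows: pd.DataFrame, min_surveys: int = MIN_SURVEYS_PER_TAXON
) -> pd.DataFrame:
    """Mean ± SE percent bleached per taxon per island.

    Taxa observed on fewer than ``min_surveys`` surveys within an island are
    dropped from that island's table (rare-taxon reporting rule).
    """
    if min_surveys < 1:
        raise ValueError("min_surveys must be >= 1")
    grouped = rows.groupby(["island", "taxon"])["taxon_pct_bleached"]
    summary = grouped.agg(
        n_surveys="count",
        mean_pct_bleached="mean",
        se_pct_bleached=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
    ).reset_index()
    kept = summary[summary["n_surveys"] >= min_surveys].reset_index(drop=True)
    dropped = len(summary) - len(kept)
    if dropped:
        logger.info("dropped %d island-taxon groups below %d surveys", dropped, min_surveys)
    return kept


def score_surveys(
    survey_rows: pd.DataFrame,
    table: SusceptibilityTable,
    total_cover_col: str = "total_cover",
) -> pd.DataFrame:
    """Compute BS for every survey in a long (survey x taxon) table.

    Surveys with zero total cover are excluded with a logged reason; the
    returned frame has one row per scoreable survey.
    """
    out = []
    for survey_id, g in survey_rows.groupby("survey_id", sort=False):
        total = float(g[total_cover_col].iloc[0])
        if total <= 0:
            logger.info("survey %s excluded: zero live coral cover", survey_id)
            continue
        score = compute_bs(g, table, total, survey_id=str(survey_id))
        out.append(
            {"survey_id": survey_id, "total_cover": total, "n_taxa": score.n_taxa, "bs": score.bs}
        )
    return pd.DataFrame(out, columns=["survey_id", "total_cover", "n_taxa", "bs"])
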