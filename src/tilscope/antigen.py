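"""Levenshtein-ranked matching of clonotype CDR3s against an antigen table.

The most expanded clonotypes are queried against a curated database of
TCR-antigen associations (McPAS-TCR dialect): for each query/database pair
the unit-cost edit distance between CDR3 amino-acid sequences is computed on
the chain(s) both sides carry, hits are ranked by distance, and each
clonotype is called a known-antigen match (best distance within a stated
threshold) or a putative neoantigen.  The threshold is a mandatory, logged
report parameter, not a biological truth claim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tilscope.errors import ConfigError, TilscopeError
from tilscope.tenx_io import AntigenDb
from tilscope.clonotype import ClonotypeSummary

logger = logging.getLogger(__name__)

CHAIN_POLICIES = ("beta_only", "alpha_only", "best_of_both")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions).

    Standard two-row dynamic program; empty strings are allowed and any
    alphabet is accepted.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):  # keep the inner row short
        a, b = b, a
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(
                min(
                    previous[j] + 1,  # deletion
                    current[j - 1] + 1,  # insertion
                    previous[j - 1] + (ca != cb),  # substitution
                )
            )
        previous = current
    return previous[-1]


@dataclass
class AntigenCallConfig:
    """Known-antigen call parameters.

    max_distance : best edit distance at or below which a clonotype counts
        as matching a known antigen (default 0 = exact; slack configurable).
    chain_policy : which CDR3 chain(s) to compare; ``best_of_both`` takes the
        minimum distance over the chains both sides carry.
    """

    max_distance: int = 0
    chain_policy: str = "best_of_both"

    def __post_init__(self):
        if self.max_distance < 0:
            raise ConfigError("max_distance must be >= 0")
        if self.chain_policy not in CHAIN_POLICIES:
            raise ConfigError(
                f"chain_policy must be one of {CHAIN_POLICIES}, got "
                f"{self.chain_policy!r}"
            )


@dataclass
class MatchResult:
    """Distance-ranked database hits for a set of query clonotypes.

    hits : DataFrame with one row per (query, db row) pair, sorted within
        each query by (distance, db row order) and ranked 1..m without gaps.
    unmatched_queries : query keys with no comparable database row.
    """

    hits: pd.DataFrame
    unmatched_queries: list


def _clean(seq: str) -> str:
    return str(seq).strip().upper()


def _query_chains(key: str) -> dict:
    """Split a clonotype key into its per-chain CDR3 lists."""
    chains = {"TRA": [], "TRB": []}
    for token in key.split(";"):
        if ":" in token:
            chain, cdr3 = token.split(":", 1)
            if chain in chains and cdr3:
                chains[chain].append(_clean(cdr3))
    return chains


def match_clonotypes(
    summary: ClonotypeSummary,
    db: AntigenDb,
    config: AntigenCallConfig | None = None,
    top_n: int = 10,
) -> MatchResult:
    """Match the most expanded clonotypes against the antigen database.

    Queries are the ``top_n`` ranked clonotypes (default 10).  For each
    query and each database row carrying the relevant chain, the edit
    distance is computed between cleaned (uppercased, stripped) CDR3s; under
    ``best_of_both`` the minimum over chains present on both sides is used,
    recording the winning chain (beta on ties).  Database rows lacking every
    comparable chain are excluded from that query's ranking; queries with no
    comparable rows at all are flagged.

    Raises
    ------
    TilscopeError
        If the database is empty.
    """
    config = config or AntigenCallConfig()
    if len(db) == 0:
        raise TilscopeError("antigen database is empty")

    want_alpha = config.chain_policy in ("alpha_only", "best_of_both")
    want_beta = config.chain_policy in ("beta_only", "best_of_both")

    rows = []
    unmatched = []
    queries = summary.table.nsmallest(top_n, "rank")
    for _, query in queries.iterrows():
        chains = _query_chains(query["key"])
        any_hit = False
        for db_idx, rec in db.df.iterrows():
            candidates = []  # (distance, chain) with beta preferred on ties
            db_beta = _clean(rec["cdr3_beta_aa"])
            db_alpha = _clean(rec["cdr3_alpha_aa"])
            if want_beta and db_beta and chains["TRB"]:
                candidates.append(
                    (min(levenshtein(q, db_beta) for q in chains["TRB"]), "beta")
                )
            if want_alpha and db_alpha and chains["TRA"]:
                candidates.append(
                    (min(levenshtein(q, db_alpha) for q in chains["TRA"]), "alpha")
                )
            if not candidates:
                continue
            any_hit = True
            distance, chain = min(candidates, key=lambda c: (c[0], c[1] != "beta"))
            rows.append(
                {
                    "query_key": query["key"],
                    "query_rank": int(query["rank"]),
                    "chain": chain,
                    "distance": int(distance),
                    "db_row": int(db_idx),
                    "antigen_protein": rec["antigen_protein"],
                    "epitope_peptide": rec["epitope_peptide"],
                    "pathology": rec["pathology"],
                    "category": rec["category"],
                }
            )
        if not any_hit:
            unmatched.append(query["key"])
            logger.warning("clonotype %r: no comparable antigen DB rows", query["key"])

    hits = pd.DataFrame(
        rows,
        columns=[
            "query_key",
            "query_rank",
            "chain",
            "distance",
            "db_row",
            "antigen_protein",
            "epitope_peptide",
            "pathology",
            "category",
        ],
    )
    if len(hits):
        hits = hits.sort_values(
            ["query_rank", "distance", "db_row"], kind="stable"
        ).reset_index(drop=True)
        hits["match_rank"] = hits.groupby("query_key", sort=False).cumcount() + 1
    else:
        hits["match_rank"] = pd.Series(dtype=int)
    return MatchResult(hits=hits, unmatched_queries=unmatched)


def classify_antigen_status(
    matches: MatchResult,
    queries,
    config: AntigenCallConfig | None = None,
) -> tuple:
    """Call each queried clonotype known-antigen vs putative neoantigen.

    A clonotype is ``known_antigen`` iff its best hit distance is at most
    ``max_distance``; clonotypes above the threshold — or with no comparable
    hit at all — are ``putative_neoantigen``.

    Parameters
    ----------
    matches : MatchResult
    queries : sequence of clonotype keys that were queried.
    config : AntigenCallConfig

    Returns
    -------
    (status, fractions)
        ``status`` is a DataFrame (key, best_distance, status); ``fractions``
        a dict of percent known / neoantigen over the queried clonotypes,
        annotated with the threshold used.
    """
    config = config or AntigenCallConfig()
    best = (
        matches.hits.groupby("query_key")["distance"].min()
        if len(matches.hits)
        else pd.Series(dtype=int)
    )
    records = []
    for key in queries:
        d = best.get(key)
        known = d is not None and d <= config.max_distance
        records.append(
            {
                "key": key,
                "best_distance": None if d is None else int(d),
                "status": "known_antigen" if known else "putative_neoantigen",
            }
        )
    status = pd.DataFrame(records, columns=["key", "best_distance", "status"])
    n = len(status)
    n_known = int((status["status"] == "known_antigen").sum())
    fractions = {
        "known_antigen_pct": 100.0 * n_known / n if n else 0.0,
        "putative_neoantigen_pct": 100.0 * (n - n_known) / n if n else 0.0,
        "max_distance": config.max_distance,
        "chain_policy": config.chain_policy,
    }
    logger.info(
        "antigen calls at max_distance=%d: %.1f%% known, %.1f%% putative neoantigen",
        config.max_distance,
        fractions["known_antigen_pct"],
        fractions["putative_neoantigen_pct"],
    )
    return status, fractions
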