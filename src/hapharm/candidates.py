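"""Poisson zero-homozygote scan for potentially harmful alleles.

For an allele at frequency ``q`` among ``N`` diploid individuals, the
expected number of homozygotes under random mating is ``E[H] = q**2 * N``
and, treating the homozygote count as Poisson, the probability of seeing
none is ``P(O[H] = 0 | E[H]) = exp(-E[H])``.

Two complementary flagging directions are implemented:

``rare``
    Flags alleles with ``p_zero > 1 - alpha`` — alleles so rare that
    absence of homozygotes is the overwhelmingly likely outcome.  At
    ``alpha = 0.05`` and ``N = 471`` this admits alleles with at most 9
    copies, reproducing the copy-number profile of candidate lists built
    on small pedigrees.  Homozygote carriers are not excluded.

``depleted``
    Flags alleles with ``p_zero < alpha`` *and* zero observed homozygotes
    — a frequency high enough that the missing homozygotes are unlikely
    to be a chance absence, the classical signature of a recessive lethal.

Both are kept because the two readings answer different questions: ``rare``
reproduces descriptive candidate tables, ``depleted`` is the statistically
powered lethal scan.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "expected_homozygotes",
    "prob_zero_homozygotes",
    "classify_candidates",
    "cross_scope_comparison",
    "max_candidate_copy_number",
    "COPY_BINS",
]

DIRECTIONS = ("rare", "depleted")

#: Copy-number histogram bins used in candidate summaries.
COPY_BINS = ("1", "2", "3-4", "5+")


def expected_homozygotes(q: float, n: int) -> float:
    """Expected homozygote count ``E[H] = q**2 * N``."""
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    if n < 1:
        raise ValueError("N must be >= 1")
    return q * q * n


def prob_zero_homozygotes(e_h: float) -> float:
    """Poisson probability of zero homozygotes, ``exp(-E[H])``."""
    if e_h < 0:
        raise ValueError("E[H] must be non-negative")
    return math.exp(-e_h)


def classify_candidates(
    stats: pd.DataFrame, alpha: float = 0.05, direction: str = "rare"
) -> pd.DataFrame:
    """Flag candidate harmful alleles in one scope's statistics frame.

    ``stats`` needs columns ``block_id, code, scope, copies, q, hom_count,
    N``.  Adds ``e_h, p_zero, alpha, direction, is_candidate``.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    out = stats.copy()
    out["e_h"] = out["q"] ** 2 * out["N"]
    out["p_zero"] = np.exp(-out["e_h"])
    out["alpha"] = alpha
    out["direction"] = direction
    if direction == "rare":
        out["is_candidate"] = out["p_zero"] > 1 - alpha
    else:
        out["is_candidate"] = (out["p_zero"] < alpha) & (out["hom_count"] == 0)
    return out


def max_candidate_copy_number(
    n: int, alpha: float = 0.05, direction: str = "rare"
) -> int:
    """Largest copy count still flagged under ``rare`` at sample size ``n``.

    Computed by scanning copy counts through :func:`classify_candidates`
    until the flag drops; returns 0 if even a single copy is not flagged.
    """
    if direction != "rare":
        raise ValueError("copy ceiling is defined for the rare direction only")
    last = 0
    for copies in range(1, 2 * n + 1):
        q = copies / (2 * n)
        row = pd.DataFrame(
            {
                "block_id": ["LB0"],
                "code": [101],
                "scope": ["WP"],
                "copies": [copies],
                "q": [q],
                "hom_count": [0],
                "N": [n],
            }
        )
        if classify_candidates(row, alpha, "rare")["is_candidate"].iloc[0]:
            last = copies
        else:
            break
    return last


def _copy_histogram(copies: pd.Series) -> dict[str, int]:
    return {
        "1": int((copies == 1).sum()),
        "2": int((copies == 2).sum()),
        "3-4": int(copies.between(3, 4).sum()),
        "5+": int((copies >= 5).sum()),
    }


def cross_scope_comparison(calls: Mapping[str, pd.DataFrame]) -> dict:
    """Summarize candidate calls across scopes.

    For every scope: total alleles, candidate count, number of blocks
    carrying a candidate and a copy-number histogram of candidates
    (1 / 2 / 3-4 / 5+ copies).  Additionally lists alleles that are
    candidates in some cohort but not at the whole-population level.
    """
    summary: dict = {"scopes": {}}
    wp_cands: set[tuple[str, int]] = set()
    if "WP" in calls:
        wp = calls["WP"]
        wp_cands = set(
            map(tuple, wp.loc[wp["is_candidate"], ["block_id", "code"]].itertuples(index=False))
        )
    cohort_not_wp = set()
    for scope, df in calls.items():
        cand = df[df["is_candidate"]]
        summary["scopes"][scope] = {
            "total_alleles": int(len(df)),
            "candidates": int(len(cand)),
            "candidate_blocks": int(cand["block_id"].nunique()),
            "copy_histogram": _copy_histogram(cand["copies"]),
        }
        if scope != "WP":
            for key in map(tuple, cand[["block_id", "code"]].itertuples(index=False)):
                if key not in wp_cands:
                    cohort_not_wp.add((scope,) + key)
    summary["cohort_candidates_not_wp"] = [
        {"scope": s, "block_id": b, "code": int(c)}
        for s, b, c in sorted(cohort_not_wp)
    ]
    return summary
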