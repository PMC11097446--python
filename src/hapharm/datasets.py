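"""Bundled reference tables from the Gochu Asturcelta pig pedigree study
population (471 genotyped individuals, 4,470 linkage blocks).

These small tables let summary arithmetic be reproduced without the full
genotype download: the per-block coordinates of the 17 segregating
candidate blocks, and the population-level tally counts.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["segregant_blocks", "SUMMARY_COUNTS", "COHORT_SIZES"]

#: Individuals per cohort (BP, G12, G23, G3) and whole population.
COHORT_SIZES = {"BP": 10, "G12": 52, "G23": 281, "G3": 128, "WP": 471}

#: Population-level tallies from the reference pedigree analysis.
SUMMARY_COUNTS = {
    "n_individuals": 471,
    "n_blocks": 4470,
    "alleles_wp": 16981,
    "candidates_wp": 5466,
    "candidate_copies_wp": 8587,
    "candidate_blocks_wp": 2031,
    "candidates_one_copy": 3995,
    "candidates_two_copies": 794,
    "candidates_three_four_copies": 445,
    "candidates_five_plus_copies": 232,
    "alleles_single_cohort": 4610,
    "mismatch_alleles": 67742,
    "blocks_with_mismatch": 3405,
    "mismatch_offspring": 63016,
    "mismatch_father": 2556,
    "mismatch_mother": 2170,
    "candidates_no_ancestor": 5169,
    "candidates_parent_only": 188,
    "candidates_grandparent_only": 43,
    "candidates_parent_and_grandparent": 66,
    "candidates_segregant": 17,
    "segregant_copies": 111,
}

_SEGREGANT_BLOCKS_TSV = """\
block_id\tchrom\tstart_bp\tend_bp\talleles\thom_genotypes
LB1260\t4\t19354979\t19414016\t6\t127
LB1271\t4\t22309905\t22377024\t4\t160
LB1781\t6\t9991623\t10005114\t3\t220
LB1788\t6\t12126135\t12135042\t3\t222
LB3444\t13\t138485747\t138569542\t6\t229
LB3445\t13\t139136979\t139523268\t12\t113
LB3446\t13\t141327231\t141490185\t10\t115
LB3448\t13\t147919800\t147971622\t4\t204
LB3449\t13\t148026119\t148049808\t4\t238
LB3450\t13\t150830656\t150866098\t6\t264
LB3452\t13\t151058135\t151193312\t7\t179
LB3453\t13\t151284389\t151366353\t6\t242
LB3495\t13\t169746824\t169879566\t7\t265
LB3515\t13\t176103740\t176292748\t6\t163
LB3525\t13\t179090359\t179263134\t9\t231
LB3526\t13\t180091685\t180125782\t3\t260
LB3529\t13\t180324134\t180433044\t5\t210
"""


def segregant_blocks() -> pd.DataFrame:
    """Coordinates and allele counts of the 17 segregating candidate blocks.

    Columns: ``block_id, chrom, start_bp, end_bp, alleles, hom_genotypes``.
    Coordinates are 1-based positions of the first and last member SNP;
    block length is ``end_bp - start_bp``.
    """
    return pd.read_csv(io.StringIO(_SEGREGANT_BLOCKS_TSV), sep="\t")
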