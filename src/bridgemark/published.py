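"""Published genome-wide summary tables from the pepper (Capsicum)
two-accession resequencing comparison that this pipeline emulates.

These are printed counts, usable as inputs for arithmetic checks (densities,
size fractions, marker polymorphism rates) without access to the raw reads.
Comparisons are keyed "<accession>_vs_<reference-or-accession>".
"""

from __future__ import annotations

#: Assembled chromosome lengths (Mb) of the CM334 reference used for densities.
CHROMOSOME_LENGTHS_MB: dict[str, float] = {
    "Chr01": 272.7, "Chr02": 171.1, "Chr03": 257.9, "Chr04": 222.6,
    "Chr05": 233.5, "Chr06": 236.9, "Chr07": 231.9, "Chr08": 145.1,
    "Chr09": 252.8, "Chr10": 233.6, "Chr11": 259.7, "Chr12": 235.7,
}

#: Per-chromosome InDel counts for the three comparisons.
CHROMOSOME_COUNTS: dict[str, dict[str, int]] = {
    "PBC688_vs_CM334": {
        "Chr01": 152473, "Chr02": 112170, "Chr03": 163193, "Chr04": 129116,
        "Chr05": 135960, "Chr06": 141153, "Chr07": 145457, "Chr08": 88291,
        "Chr09": 146724, "Chr10": 143004, "Chr11": 168460, "Chr12": 138769,
    },
    "G29_vs_CM334": {
        "Chr01": 66466, "Chr02": 40498, "Chr03": 44010, "Chr04": 27962,
        "Chr05": 35179, "Chr06": 40996, "Chr07": 57444, "Chr08": 13647,
        "Chr09": 52697, "Chr10": 41440, "Chr11": 82799, "Chr12": 30385,
    },
    "PBC688_vs_G29": {
        "Chr01": 159094, "Chr02": 110357, "Chr03": 158889, "Chr04": 125802,
        "Chr05": 134106, "Chr06": 137156, "Chr07": 140859, "Chr08": 86696,
        "Chr09": 150116, "Chr10": 138197, "Chr11": 173795, "Chr12": 136789,
    },
}

#: Printed totals and overall densities (InDels/Mb) for the three comparisons.
PUBLISHED_TOTALS: dict[str, int] = {
    "PBC688_vs_CM334": 1_664_770,
    "G29_vs_CM334": 533_523,
    "PBC688_vs_G29": 1_651_856,
}
PUBLISHED_DENSITIES: dict[str, float] = {
    "PBC688_vs_CM334": 604.6,
    "G29_vs_CM334": 193.8,
    "PBC688_vs_G29": 599.9,
}

#: Size histograms: counts for 1..10 bp and the >=11 bp bin, with the printed
#: rounded per-size ratios (percent).
SIZE_HISTOGRAMS: dict[str, dict[int, int]] = {
    # the >=11 bin is stored under key 11 (counts for 11..49 are not printed
    # individually)
    "PBC688_vs_CM334": {
        1: 1133853, 2: 193287, 3: 79302, 4: 49406, 5: 26706,
        6: 25864, 7: 16295, 8: 16777, 9: 16396, 10: 13945, 11: 92939,
    },
    "G29_vs_CM334": {
        1: 345796, 2: 62199, 3: 25317, 4: 16860, 5: 9614,
        6: 9431, 7: 6322, 8: 6475, 9: 6348, 10: 5459, 11: 39702,
    },
    "PBC688_vs_G29": {
        1: 1129627, 2: 186832, 3: 79602, 4: 49560, 5: 27140,
        6: 25056, 7: 15470, 8: 16107, 9: 15547, 10: 13361, 11: 93554,
    },
}
SIZE_RATIOS_PCT: dict[str, dict[int, float]] = {
    "PBC688_vs_G29": {
        1: 68.4, 2: 11.3, 3: 4.8, 4: 3.0, 5: 1.6,
        6: 1.5, 7: 0.9, 8: 1.0, 9: 0.9, 10: 0.8, 11: 5.7,
    },
}

#: Genic InDel bookkeeping: counts of InDels in gene regions.
GENIC_COUNTS: dict[str, tuple[int, int]] = {
    # comparison -> (genic InDels, total InDels)
    "PBC688_vs_CM334": (63_992, 1_664_770),
    "G29_vs_CM334": (23_897, 533_523),
    "PBC688_vs_G29": (58_944, 1_651_856),
}

#: Marker validation outcome counts between the two resequenced accessions:
#: 1605 designed; codominant / monomorphic / dominant / failed-to-amplify.
MARKER_OUTCOMES: dict[str, int] = {
    "designed": 1605,
    "codominant": 1172,
    "monomorphic": 298,
    "dominant": 90,
    "failed": 45,
}

#: Species-panel bookkeeping for the three diagnostic markers: accessions
#: genotyped, band alleles observed per locus.
PANEL_ACCESSIONS = 63
PANEL_ALLELES_PER_LOCUS = (5, 6, 5)
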