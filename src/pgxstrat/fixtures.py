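"""Bundled demonstration tables of group-divergent pharmacogenomic variants.

``demo_annotation`` holds 20 clinically annotated variants with
PharmGKB-style gene-drug associations and evidence levels, all known to
be strongly divergent between self-identified race/ethnicity groups in
large US cohorts. Four of them carry curated toxicity annotations with a
known mode of effect and effect allele; ``demo_group_frequencies`` holds
their published per-group effect-allele frequencies, which together feed
the worked excess-adverse-reaction examples in the README.
"""

from __future__ import annotations

import pandas as pd

from .io_formats import ANNOTATION_COLUMNS, FREQUENCY_COLUMNS

# variant_id, rsid, gene, drugs, evidence, association, mode, effect allele
_ANNOTATION_ROWS = [
    ("chr1:97883329:A:G", "rs1801265", "DPYD",
     "capecitabine,fluorouracil", "1A", "other", "unknown", "G"),
    ("chr4:88131171:G:T", "rs2231142", "ABCG2",
     "rosuvastatin", "1A", "other", "unknown", "T"),
    ("chr19:15879621:C:T", "rs2108622", "CYP4F2",
     "warfarin", "1A", "other", "unknown", "T"),
    ("chr19:39248147:C:T", "rs12979860", "IFNL3,IFNL4",
     "peginterferon alfa-2a,peginterferon alfa-2b,ribavirin,telaprevir,boceprevir",
     "1A", "other", "unknown", "T"),
    ("chr16:31093557:G:A", "rs9934438", "VKORC1",
     "warfarin", "1B", "other", "unknown", "A"),
    ("chr16:31096368:C:T", "rs9923231", "VKORC1",
     "warfarin", "1B", "toxicity", "dominant", "T"),
    ("chr19:39252525:T:G", "rs8099917", "IFNL3",
     "interferons,peginterferon alfa-2a,peginterferon alfa-2b,ribavirin",
     "1B", "other", "unknown", "G"),
    ("chr16:31091000:C:T", "rs7294", "VKORC1",
     "warfarin", "1B", "other", "unknown", "T"),
    ("chr1:11796321:G:A", "rs1801133", "MTHFR",
     "methotrexate", "2A", "toxicity", "dominant", "A"),
    ("chr7:99767460:G:A", "rs4646437", "CYP3A4",
     "tacrolimus", "2A", "toxicity", "dominant", "A"),
    ("chr21:45537880:T:C", "rs1051266", "SLC19A1",
     "methotrexate", "2A", "other", "unknown", "C"),
    ("chr12:21178615:T:C", "rs4149056", "SLCO1B1",
     "hmg coa reductase inhibitors", "2A", "other", "unknown", "C"),
    ("chr12:111803962:G:A", "rs671", "ALDH2",
     "ethanol", "2B", "other", "unknown", "A"),
    ("chr6:39357302:A:G", "rs20455", "KIF6",
     "pravastatin", "2B", "other", "unknown", "G"),
    ("chr2:166053034:C:T", "rs3812718", "SCN1A",
     "carbamazepine", "2B", "other", "unknown", "T"),
    ("chr15:78590583:G:A", "rs16969968", "CHRNA5",
     "nicotine", "2B", "other", "unknown", "A"),
    ("chr15:74720644:T:C", "rs1048943", "CYP1A1",
     "capecitabine,docetaxel", "3", "other", "unknown", "C"),
    ("chr16:31087690:T:C", "rs11150606", "VKORC1",
     "warfarin", "3", "other", "unknown", "C"),
    ("chr2:101806532:T:C", "rs4550690", "MAP4K4",
     "anastrozole,exemestane", "3", "other", "unknown", "C"),
    ("chr8:42298528:A:G", "rs9694958", "IKBKB",
     "gefitinib", "3", "toxicity", "recessive", "A"),
]

# Published per-group effect-allele frequencies for the four toxicity
# variants (effect allele as annotated above; note rs9694958's effect
# allele is the reference allele A).
_FREQUENCY_ROWS = [
    ("chr7:99767460:G:A", "rs4646437", "Black", "A", 0.725),
    ("chr7:99767460:G:A", "rs4646437", "White", "A", 0.105),
    ("chr16:31096368:C:T", "rs9923231", "Asian", "T", 0.674),
    ("chr16:31096368:C:T", "rs9923231", "White", "T", 0.338),
    ("chr1:11796321:G:A", "rs1801133", "Black", "A", 0.104),
    ("chr1:11796321:G:A", "rs1801133", "White", "A", 0.348),
    ("chr8:42298528:A:G", "rs9694958", "Black", "A", 0.333),
    ("chr8:42298528:A:G", "rs9694958", "White", "A", 0.920),
]


def demo_annotation() -> pd.DataFrame:
    """The 20-variant demonstration annotation table."""
    return pd.DataFrame(_ANNOTATION_ROWS, columns=ANNOTATION_COLUMNS)


def demo_group_frequencies() -> pd.DataFrame:
    """Published per-group effect-allele frequencies for the demo toxicity variants.

    ``n_called`` is 0 as a sentinel: these frequencies are literature
    values, not computed from a genotype matrix in this package.
    """
    df = pd.DataFrame(
        _FREQUENCY_ROWS, columns=["variant_id", "rsid", "group", "allele", "freq"]
    )
    df["n_called"] = 0
    return df[FREQUENCY_COLUMNS]
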