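"""Published result tables for the *Neotermes binovatus* worker/soldier
metatranscriptome, used as inputs for tabulation cross-checks.

Three small tables from the published study of caste-biased host-flagellate
expression in *N. binovatus* are embedded here:

* the per-order, per-gene-class counts of flagellate transcript
  identifications (433 transcripts across four flagellate orders plus an
  order-unclassified pool);
* the ten genus-level 18S rRNA identifications (*Devescovina*, *Oxymonas*,
  *Blattamonas*) with best-hit percent identity and caste TMM means;
* the twelve lasso biomarker transcripts with coefficients, caste TMM
  means and DET flags.

They serve as fixed inputs to the tabulation and report-join operations —
reconstructing per-transcript calls from the printed counts and verifying
that the package reproduces the printed totals — not as fitted quantities.
"""

from __future__ import annotations

import pandas as pd

from .source_classifier import FLAGELLATE, SourceCall
from .syndata import generate_taxonomy

# gene class x order counts of flagellate transcript identifications;
# columns: Cristamonadida, Oxymonadida, Trichomonadida, Tritrichomonadida,
# unclassified order
FLAGELLATE_ORDER_GENE_COUNTS: dict[str, tuple[int, int, int, int, int]] = {
    "18S rRNA": (10, 7, 2, 0, 5),
    "actin": (63, 0, 4, 11, 76),
    "alpha tubulin": (0, 1, 0, 1, 48),
    "beta tubulin": (0, 0, 0, 0, 56),
    "EF1a": (16, 0, 1, 0, 10),
    "GAPDH": (5, 0, 0, 0, 16),
    "others": (0, 0, 3, 0, 98),
}
_COUNT_ORDERS = ("Cristamonadida", "Oxymonadida", "Trichomonadida",
                 "Tritrichomonadida", None)

# genus-level identifications: (gene, genus, order, best-hit pident,
# mean worker TMM, mean soldier TMM, adjusted p)
GENUS_LEVEL_CALLS: list[tuple[str, str, str, float, float, float, float]] = [
    ("18S rRNA", "Devescovina", "Cristamonadida", 92.55, 1011.79, 375.31, 0.55),
    ("18S rRNA", "Devescovina", "Cristamonadida", 95.75, 105.92, 64.66, 0.78),
    ("18S rRNA", "Devescovina", "Cristamonadida", 95.67, 200.04, 88.15, 0.59),
    ("18S rRNA", "Devescovina", "Cristamonadida", 91.80, 197.95, 175.36, 0.95),
    ("18S rRNA", "Oxymonas", "Oxymonadida", 94.78, 547.68, 908.43, 0.71),
    ("18S rRNA", "Oxymonas", "Oxymonadida", 92.41, 90.92, 178.40, 0.59),
    ("18S rRNA", "Oxymonas", "Oxymonadida", 96.83, 147.28, 271.46, 0.70),
    ("18S rRNA", "Oxymonas", "Oxymonadida", 97.46, 869.33, 1632.84, 0.66),
    ("18S rRNA", "Oxymonas", "Oxymonadida", 97.38, 442.22, 830.14, 0.65),
    ("18S rRNA", "Blattamonas", "Oxymonadida", 99.12, 1468.43, 2481.67, 0.71),
]

# lasso biomarker transcripts: (description, putative source, coefficient,
# mean worker TMM, mean soldier TMM, DET flag)
BIOMARKER_TABLE: list[tuple[str, str, float, float, float, str]] = [
    ("inositol 1,4,5-trisphosphate receptor", "termite",
     -0.00015, 97.58, 18.41, "no"),
    ("RIC3", "termite", 0.00121, 803.25, 2862.81, "yes"),
    ("TBX20", "termite", 0.01148, 24.28, 127.13, "yes"),
    ("CLIP2", "termite", 0.00022, 187.64, 1157.88, "yes"),
    ("periaxin", "termite", -0.00178, 172.28, 3.17, "yes"),
    ("RMDN1", "termite", -0.00261, 346.49, 30.11, "yes"),
    ("CLIP2-like", "unclear", 0.00105, 656.38, 3365.92, "yes"),
    ("CTL2", "termite", -0.00071, 960.42, 141.31, "yes"),
    ("serine/threonine-protein kinase", "unclear",
     4.56096, 125.45, 1099.15, "no"),
    ("Kazal-type serine protease inhibitor", "unclear",
     1.95818, 149.86, 1717.32, "yes"),
    ("SNX29", "termite", -0.01008, 173.60, 12.24, "yes"),
    ("PTL", "termite", 0.00021, 287.63, 2320.95, "yes"),
]


def reference_flagellate_calls() -> tuple[list[SourceCall], dict[str, str]]:
    """Reconstruct per-transcript flagellate calls from the published
    per-order, per-gene-class counts.

    Returns one FLAGELLATE :class:`SourceCall` per counted transcript
    (with the order taxid set where classified) plus the matching
    transcript -> gene-class map, suitable for ``tabulate_sources``.
    """
    tax = generate_taxonomy()
    calls: list[SourceCall] = []
    gene_labels: dict[str, str] = {}
    i = 0
    for gene, row in FLAGELLATE_ORDER_GENE_COUNTS.items():
        for order_name, count in zip(_COUNT_ORDERS, row):
            taxid = tax.taxid_of(order_name) if order_name else None
            for _ in range(count):
                tid = f"ref{i:04d}"
                calls.append(SourceCall(tid, FLAGELLATE, order=taxid))
                gene_labels[tid] = gene
                i += 1
    return calls, gene_labels


def reference_genus_calls() -> tuple[list[SourceCall], dict[str, str]]:
    """Per-transcript genus-resolved calls from the published genus table."""
    tax = generate_taxonomy()
    calls: list[SourceCall] = []
    gene_labels: dict[str, str] = {}
    for i, (gene, genus, order, *_rest) in enumerate(GENUS_LEVEL_CALLS):
        tid = f"gen{i:02d}"
        calls.append(SourceCall(tid, FLAGELLATE,
                                order=tax.taxid_of(order),
                                genus=tax.taxid_of(genus)))
        gene_labels[tid] = gene
    return calls, gene_labels


def reference_biomarker_report() -> pd.DataFrame:
    """The published biomarker table in the package's report format."""
    return pd.DataFrame(
        [{"transcript": desc, "putative_source": src, "coefficient": coef,
          "avg_worker_tmm": w, "avg_soldier_tmm": s, "det": det}
         for desc, src, coef, w, s, det in BIOMARKER_TABLE])
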