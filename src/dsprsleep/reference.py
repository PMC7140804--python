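"""Bundled reference inputs from the DSPR sleep mapping study.

The enrichment and reporting stages consume two small published summaries as
*inputs* (they are not recomputed here):

* the 12 QTL-group intervals mapped for the eight sleep/activity traits in
  the DSPR F1 panel (group id, contributing trait codes, chromosome arm,
  interval size in Mb);
* the count of unique variants associated with the same traits by the
  independent DGRP inbred-line GWAS, used for the variants-in-intervals
  enrichment expectation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: unique sleep/activity-associated variants reported by the DGRP GWAS
DGRP_SLEEP_GWAS_VARIANTS = 2427

#: Drosophila melanogaster release-6 euchromatic genome size (Mb) used when
#: expressing QTL-group span as a genome fraction
EUCHROMATIC_GENOME_MB = 126.33


def load_reference_qtl_groups() -> pd.DataFrame:
    """The 12 reference QTL-group intervals (group, phenotypes, chrom, size_mb)."""
    with resources.files("dsprsleep.data").joinpath(
        "qtl_groups_dspr_sleep.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def reference_group_span_mb() -> float:
    """Total genomic span of the reference QTL groups, in Mb."""
    return float(load_reference_qtl_groups()["size_mb"].sum())


def reference_covered_fraction() -> float:
    """Fraction of the euchromatic genome covered by the reference groups."""
    return reference_group_span_mb() / EUCHROMATIC_GENOME_MB
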