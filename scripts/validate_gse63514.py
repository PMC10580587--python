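#!/usr/bin/env python
"""OPTIONAL, NETWORKED validation against the deposited cervical-cancer cohort.

This script is deliberately separated from the test suite and the acceptance
script: it needs internet access to fetch the GEO series matrix for GSE63514
(128 cervical samples, Affymetrix U133 Plus 2.0) and checks the pipeline's
qualitative claims on the real cohort:

  * CSRP2BP is up-regulated in cancer vs normal at p <= 0.05,
  * CSRP2BP's expression correlates positively with the ssGSEA EMT score and
    passes the joint screen (p <= 0.05, |SCC| >= 0.3),
  * CSRP2BP appears in the top-30%-by-R / positively-correlated overlap.

It requires a local GMT with an EMT gene set (e.g. the MSigDB hallmark EMT
set) and a probe-to-symbol mapping, both of which the user must supply; the
exact numeric values printed in the literature depend on the MSigDB release
and enrichment variant used and are not asserted here.

Usage:
  python scripts/validate_gse63514.py --emt-gmt hallmark_emt.gmt \
      --acetyl-gmt acetyltransferase.gmt --workdir scratch/geo
"""

from __future__ import annotations

import argparse
import gzip
import io
import urllib.request
from pathlib import Path

import numpy as np
import pandas as pd

SERIES_MATRIX_URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/GSE63nnn/GSE63514/matrix/"
    "GSE63514_series_matrix.txt.gz"
)


def fetch_series_matrix(workdir: Path) -> Path:
    workdir.mkdir(parents=True, exist_ok=True)
    dest = workdir / "GSE63514_series_matrix.txt.gz"
    if not dest.exists():
        print(f"downloading {SERIES_MATRIX_URL} ...")
        urllib.request.urlretrieve(SERIES_MATRIX_URL, dest)
    return dest


def parse_series_matrix(path: Path) -> tuple[pd.DataFrame, pd.Series]:
    """Return (probes x samples table, per-sample stage labels)."""
    titles = None
    with gzip.open(path, "rt") as fh:
        lines = fh.readlines()
    table_start = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
    table_end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    for line in lines[:table_start]:
        if line.startswith("!Sample_title"):
            titles = [t.strip().strip('"') for t in line.split("\t")[1:]]
    table = pd.read_csv(
        io.StringIO("".join(lines[table_start + 1 : table_end])), sep="\t", index_col=0
    )
    stages = pd.Series(titles, index=table.columns).str.lower()

    def classify(title: str) -> str:
        if "normal" in title:
            return "normal"
        if "cin1" in title:
            return "CIN1"
        if "cin2" in title:
            return "CIN2"
        if "cin3" in title:
            return "CIN3"
        return "cancer"

    return table, stages.map(classify)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--emt-gmt", required=True)
    parser.add_argument("--acetyl-gmt", required=True)
    parser.add_argument("--probe-map", default=None,
                        help="TSV probe_id -> gene_symbol; probes kept as-is if omitted")
    parser.add_argument("--workdir", type=Path, default=Path("scratch/geo"))
    args = parser.parse_args()

    from acetylprio.de_ranking import differential_rank, select_top
    from acetylprio.emt_screen import screen
    from acetylprio.io_formats import ExpressionMatrix, SampleAnnotation, read_gmt
    from acetylprio.prioritize import overlap
    from acetylprio.ssgsea import emt_scores

    table, stages = parse_series_matrix(fetch_series_matrix(args.workdir))
    if args.probe_map:
        mapping = pd.read_csv(args.probe_map, sep="\t", index_col=0).iloc[:, 0]
        table.index = table.index.map(mapping)
        table = table[table.index.notna()]
    matrix = ExpressionMatrix.from_frame(table)
    annotation = SampleAnnotation(pd.DataFrame({"stage": stages}))
    emt_set = read_gmt(args.emt_gmt).sets[0]
    acetyl = list(read_gmt(args.acetyl_gmt).sets[0].members)

    emt = emt_scores(matrix, emt_set)
    de = differential_rank(matrix, annotation, genes=acetyl)
    scr = screen(matrix, emt, acetyl)
    cand = overlap(select_top(de), scr)

    de_i = de.set_index("gene_id")
    scr_i = scr.set_index("gene_id")
    gene = "CSRP2BP"
    if gene in de_i.index:
        print(f"{gene}: DE p={de_i.loc[gene, 'p']:.3g}, log2FC={de_i.loc[gene, 'log2fc']:.3f} "
              f"(up-regulated at p<=0.05: {de_i.loc[gene, 'de_class'] == 'up'})")
        print(f"{gene}: EMT SCC={scr_i.loc[gene, 'scc']:.3f}, p={scr_i.loc[gene, 'p']:.3g} "
              f"(passes screen: {bool(scr_i.loc[gene, 'passes'])})")
        print(f"{gene} in candidate overlap: {gene in set(cand['gene_id'])}")
    else:
        print(f"{gene} not present after mapping; supply --probe-map with gene symbols")
    print(f"candidates: {list(cand['gene_id'])}")


if __name__ == "__main__":
    main()
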