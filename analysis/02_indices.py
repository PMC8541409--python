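#!/usr/bin/env python
"""Compute the per-taxon indices and per-category consensus tables.

Applies the standard FC >= 2 filter, then writes one index table
(FC, RFC, UR, S, CV, IUc counts) and one consensus table (n_ur, n_taxa, Fic)
per scope (pooled + each area) under results/, and prints the five most
salient taxa and the consensus ranking.
"""

import argparse
from pathlib import Path

from ethnosurvey import indices
from ethnosurvey.records import filter_min_citations, read_citations
from ethnosurvey.reporting import (
    export_consensus_table,
    export_index_table,
    render_consensus_table,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", type=Path, default=Path("results/simulated_citations.csv"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--min-citations", type=int, default=2)
    args = parser.parse_args()

    data = read_citations(args.input)
    filtered = filter_min_citations(data, args.min_citations)
    print(
        f"{args.input}: {data.n_interviews()} interviews, "
        f"{len(data.taxa)} taxa, {len(filtered.taxa)} with "
        f"FC >= {args.min_citations}"
    )
    args.outdir.mkdir(parents=True, exist_ok=True)
    for scope in ["all"] + sorted(filtered.areas):
        label = scope.replace(" ", "_")
        table = indices.index_table(filtered, scope)
        export_index_table(table, args.outdir / f"index_{label}.csv")
        consensus = indices.informant_consensus(filtered, scope)
        export_consensus_table(consensus, args.outdir / f"consensus_{label}.csv")
        if scope == "all":
            print("\ntop 5 taxa by RFC (pooled):")
            for row in table.head(5).itertuples(index=False):
                print(
                    f"  {row.taxon:<28} RFC={row.RFC:.2f}  S={row.S:.3f}  "
                    f"UR={row.UR}  CV={row.CV:.3f}"
                )
            print("\ninformant consensus by use category (pooled):")
            print(render_consensus_table(consensus))


if __name__ == "__main__":
    main()
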