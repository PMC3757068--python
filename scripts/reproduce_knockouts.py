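#!/usr/bin/env python
"""Reproduce genome-scale knockout shadow-price analyses (optional).

This script is NOT part of the test surface: it requires a genome-scale
SBML model (e.g. the E. coli reconstruction iJO1366 from the BiGG database)
downloaded separately, plus an explicit medium definition.  Published
minimal-media recipes do not map uniquely onto exchange-reaction bounds
(counter-ion, trace-element and gas exchanges are conventionally left
open), so the mapping is deliberately exposed as a medium TSV rather than
hard-coded; the exact file used should be reported next to any numbers
produced by this script.

Typical use::

    python scripts/reproduce_knockouts.py \
        --model iJO1366.xml \
        --medium gutnick_nh4.tsv \
        --knockout b3212 --knockout b3213 \
        --out knockout_shadow_prices.tsv

writes per-metabolite wild-type and knockout shadow prices and their
difference, restricted to metabolites whose shadow-price validity range
is at least ``--eps-range`` wide.
"""

import argparse
import sys

import pandas as pd

from fluximba.degeneracy import differential_shadow_prices
from fluximba.duality import solve_fba
from fluximba.io import read_medium, read_model
from fluximba.model import apply_medium, knockout_genes


def main(argv=None):
    parser = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter
    )
    parser.add_argument("--model", required=True, help="SBML/JSON/TSV model path")
    parser.add_argument(
        "--medium",
        required=True,
        help="medium TSV (reaction_id, lower_bound, upper_bound); exchanges "
        "absent from it are closed for uptake",
    )
    parser.add_argument(
        "--knockout",
        action="append",
        default=[],
        help="gene to delete in the knockout strain (repeatable)",
    )
    parser.add_argument("--eps-range", type=float, default=1e-6)
    parser.add_argument("--out", default="-", help="output TSV ('-' = stdout)")
    args = parser.parse_args(argv)

    model = apply_medium(read_model(args.model), read_medium(args.medium))
    primal, _ = solve_fba(model)
    if not primal.is_optimal:
        parser.error(f"wild-type FBA is {primal.status}; check the medium file")
    ko = knockout_genes(model, set(args.knockout)) if args.knockout else model
    table = differential_shadow_prices(model, ko)
    table.insert(1, "medium", args.medium)
    if args.out == "-":
        table.to_csv(sys.stdout, sep="\t", index=False)
    else:
        table.to_csv(args.out, sep="\t", index=False)
        print(f"wrote {len(table)} rows to {args.out}", file=sys.stderr)


if __name__ == "__main__":
    main()
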