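#!/usr/bin/env python
"""Optional validation against published pentamer shape tables.

The package's test suite runs entirely on synthetic tables.  If you have
the published DNAshape-derived pentamer tables (MGW and ProT as
KMER<TAB>VALUE pentamer files; Roll and HelT either pre-centered tetramer
files or the raw two-values-per-pentamer form as NAME.first.tsv /
NAME.second.tsv), this script reports the leave-one-out cross-validated
R^2 of the mononucleotide and mono+dinucleotide sequence-to-shape models
for each table, the quantities usually quoted for these data.

Usage:
    python scripts/external_validation.py --tables DIR

Expected files in DIR (any subset):
    MGW.tsv, ProT.tsv                  pentamer tables
    Roll.tsv, HelT.tsv                 centered tetramer tables, or
    Roll.first.tsv + Roll.second.tsv   raw per-pentamer step values
    HelT.first.tsv + HelT.second.tsv
"""

import argparse
import sys
from pathlib import Path

from shapereadout.seq2shape import MONO, MONO_DI, loo_cv_r2
from shapereadout.tables import (
    BASE_CENTERED,
    STEP_CENTERED,
    RawPentamerStepTable,
    center_step_table,
    read_table,
    reverse_complement_symmetrize,
)


def load_available(directory: Path):
    tables = {}
    for name in ("MGW", "ProT"):
        p = directory / f"{name}.tsv"
        if p.exists():
            tables[name] = reverse_complement_symmetrize(
                read_table(p, BASE_CENTERED, feature_name=name)
            )
    for name in ("Roll", "HelT"):
        p = directory / f"{name}.tsv"
        p1 = directory / f"{name}.first.tsv"
        p2 = directory / f"{name}.second.tsv"
        if p.exists():
            tables[name] = reverse_complement_symmetrize(
                read_table(p, STEP_CENTERED, feature_name=name)
            )
        elif p1.exists() and p2.exists():
            first = read_table(p1, BASE_CENTERED, feature_name=name)
            second = read_table(p2, BASE_CENTERED, feature_name=name)
            tables[name] = center_step_table(
                RawPentamerStepTable(name, first.values, second.values)
            )
    return tables


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--tables", required=True, type=Path, help="directory of shape tables")
    args = ap.parse_args()
    if not args.tables.is_dir():
        print(f"error: table directory {args.tables} does not exist", file=sys.stderr)
        return 2
    tables = load_available(args.tables)
    if not tables:
        print(
            f"error: no shape table files found in {args.tables} "
            "(expected MGW.tsv / ProT.tsv / Roll.tsv / HelT.tsv ...)",
            file=sys.stderr,
        )
        return 2
    print(f"{'feature':8s} {'k':>2s} {'mono R2':>9s} {'mono+di R2':>11s}")
    for name, tbl in tables.items():
        r_mono = loo_cv_r2(tbl, MONO)
        r_di = loo_cv_r2(tbl, MONO_DI)
        print(f"{name:8s} {tbl.k:2d} {r_mono:9.3f} {r_di:11.3f}")
    print(
        "\nR2 values are leave-one-out cross-validated (reverse-complement"
        " pairs held out together)."
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
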