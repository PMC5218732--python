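#!/usr/bin/env python
"""Refit the QSAR model on a user-transcribed fingerprint/affinity table.

The original training fingerprints live in a supplementary PDF and are not
bundled here.  If you transcribe them into a TSV with columns
FP1..FP6 + logRBA (one row per ligand with a measured relative binding
affinity) and save it as ``data/s2_fingerprints.tsv``, this script refits
the six-feature model and reports R^2 and leave-one-out Q^2 alongside the
shipped coefficients.

Usage:  python scripts/fit_supplementary.py [path/to/table.tsv]
"""

from __future__ import annotations

import sys
from pathlib import Path

DEFAULT = Path(__file__).resolve().parents[1] / "data" / "s2_fingerprints.tsv"


def main() -> int:
    path = Path(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT
    if not path.exists():
        print(f"table not found: {path}\n"
              "transcribe the supplementary fingerprint table to this "
              "location to run the refit (skipping).")
        return 0

    from hydroqsar.qsar import (
        FP_NAMES,
        fit_mlr,
        loo_q2,
        published_model,
        read_fingerprint_table,
    )

    X, y = read_fingerprint_table(path)
    model = fit_mlr(X, y, feature_names=FP_NAMES)
    q2 = loo_q2(X, y, feature_names=FP_NAMES)
    ref = published_model()
    print(f"n = {len(y)} ligands")
    print(f"R^2  = {model.r2:.3f}")
    print(f"Q^2  = {q2:.3f}  (leave-one-out)")
    print(f"{'bit':>5s} {'refit':>8s} {'shipped':>8s}")
    for name in FP_NAMES:
        print(f"{name:>5s} {model.coefficients[name]:8.3f} "
              f"{ref.coefficients[name]:8.3f}")
    print(f"{'C':>5s} {model.intercept:8.3f} {ref.intercept:8.3f}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
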