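#!/usr/bin/env python
"""Regenerate the reference 0.5 cm x 0.5 cm virtual liver tissue.

The tissue used by the packaged growth scenarios is fully determined by
this hard-coded seed; rerunning the script reproduces it byte-identically.

    python scripts/regenerate_manuscript_tissue.py [--out DIR]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from hepamet.params import Domain, ScenarioConfig
from hepamet.tissue_gen import generate_tissue, write_tissue

REFERENCE_SEED = 20210118


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("reference_tissue"))
    args = parser.parse_args()

    cfg = ScenarioConfig(domain=Domain(5000.0, 5000.0), seed=REFERENCE_SEED)
    tissue = generate_tissue(cfg)
    write_tissue(tissue, args.out)
    n_interior = int(tissue.lobules.interior.sum()) if tissue.lobules else 0
    print(
        f"reference tissue (seed {REFERENCE_SEED}): "
        f"{len(tissue.cvs)} central veins, {n_interior} interior lobules, "
        f"{len(tissue.parenchyma)} parenchyma agents -> {args.out}"
    )


if __name__ == "__main__":
    main()
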