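#!/usr/bin/env python
"""Subregion composition statistics with Sidak-corrected pairwise contrasts.

Assigns cells to the four territories (DMCP/LCP/TCP/aVMCP), computes
per-hemisphere densities, and runs both mixed-model pivots: subtype
differences within each subregion and subregion differences within each
subtype.
"""

from pathlib import Path

import pandas as pd

from cpmap.pipeline import RunConfig, run_subregions

HERE = Path(__file__).parent


def main() -> None:
    cfg = RunConfig.from_yaml(HERE / "00_config.yaml")
    out = run_subregions(cfg)
    omnibus = pd.read_csv(out / "composition_omnibus.csv")
    pairwise = pd.read_csv(out / "composition_pairwise.csv")
    print(omnibus[["mode", "stratum", "chi2", "df", "p"]].to_string(index=False))
    n_sig = int(pairwise["significant"].sum())
    print(f"{n_sig} / {len(pairwise)} Sidak-corrected pairwise contrasts significant at 0.05")


if __name__ == "__main__":
    main()
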