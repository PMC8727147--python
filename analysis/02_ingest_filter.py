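"""Ingest the association table into the canonical earliest-discovery pair table.

Applies the standard analysis filters — taxonomically resolved viruses only,
wild host species only, records through 2018 — then collapses duplicate
reports to one row per (host, virus) pair with its earliest discovery year
and, separately, its earliest PCR-or-isolation year (used by the snapshot
regressions). Writes results/pairs.csv.
"""

import argparse
from pathlib import Path

from virodiscover import FilterConfig, apply_filters, dedupe_to_pairs, read_associations


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="in_path", type=Path, default=Path("results/sim/associations.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/pairs.csv"))
    args = ap.parse_args()

    result = read_associations(args.in_path)
    print(f"{len(result.records)} records parsed, {len(result.rejected)} rejected")

    cfg = FilterConfig()  # resolved viruses, wild hosts, <= 2018
    kept = apply_filters(result.records, cfg)
    print(f"{len(kept)} records after filters (resolved, wild, <= {cfg.year_max})")

    pairs = dedupe_to_pairs(kept)
    strict = pairs["strict_year"].notna().sum()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pairs.to_csv(args.out, index=False)
    print(f"{len(pairs)} unique host-virus pairs ({strict} with PCR/isolation evidence)")
    print(f"  discovery years {pairs['discovery_year'].min()}-{pairs['discovery_year'].max()}")
    print(f"  written to {args.out}")


if __name__ == "__main__":
    main()
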