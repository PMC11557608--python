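#!/usr/bin/env python
"""Minimum driver nodes of the emulated networks.

Maximum matching on the bipartite out/in doubling gives the minimum
dedicated-input count; alternative minimum sets are enumerated (capped at
64) and the smallest networks are verified against the Kalman rank
condition with generic weights.
"""

import json
from pathlib import Path

from uprnet import enumerate_driver_sets, network_io, verify_driver_set
from uprnet.controllability import VERIFY_MAX_N

NETS = Path("results/networks")
OUT = Path("results/analysis")
CAP = 64


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    report = {}
    for path in sorted(NETS.glob("*.tsv")):
        name = path.stem.replace("_", " ")
        with open(path) as fh:
            g = network_io.parse_interaction_tsv(fh, 0.400)
        res = enumerate_driver_sets(g, cap=CAP)
        verified = (verify_driver_set(g, sorted(res.driver_sets[0], key=str))
                    if g.number_of_nodes() <= VERIFY_MAX_N else None)
        report[name] = {
            "driver_count": res.driver_count,
            "n_sets": len(res.driver_sets),
            "truncated": res.truncated,
            "matching_size": res.matching_size,
            "kalman_verified": verified,
            "sets": [sorted(map(str, s)) for s in res.driver_sets],
        }
        more = "+" if res.truncated else ""
        print(f"{name:<28} N_D={res.driver_count}  sets={len(res.driver_sets)}{more}")
    with open(OUT / "drivers.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    print(f"\ndriver report written to {OUT / 'drivers.json'}")


if __name__ == "__main__":
    main()
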