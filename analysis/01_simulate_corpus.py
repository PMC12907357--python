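#!/usr/bin/env python
"""Generate the synthetic VAERS-format corpus that drives the analysis.

Writes the three-file triple (data/vax/symptoms), the planted ground truth,
and a config echo under results/synthetic/.  The stated world: 10,000 DTaP
reports in a 100,000-report corpus, three planted relative risks of 3
(Febrile convulsion on Infanrix, Injection site induration on any DTaP,
Apnoea on Daptacel), short geometric onset delays with a 1% multi-year tail,
~1.5% fatal share, and injected duplicate reports.
"""

import argparse
from pathlib import Path

from dtapsafe.synthetic import SyntheticConfig, generate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "synthetic")
    args = parser.parse_args()

    config = SyntheticConfig(seed=args.seed)
    _, truth = generate(config, out_dir=args.out)
    print(f"wrote synthetic triple to {args.out}")
    print(f"planted signals ({len(truth.relative_risks)}):")
    for (exposure, pt), rr in truth.relative_risks.items():
        print(f"  {exposure} x {pt}: RR = {rr}")
    print(f"injected duplicates: {len(truth.duplicates)}")


if __name__ == "__main__":
    main()
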