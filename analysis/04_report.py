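#!/usr/bin/env python
"""Summarize a completed screen run: counts per rank, alpha1,3-specific list.

Writes report.json / report.md inside the run directory and prints the
summary.
"""

import argparse
import json
from pathlib import Path

from glycoscreen.pipeline import report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--run", type=Path, default=Path("results/screen_run"))
    args = parser.parse_args()
    summary = report(args.run)
    print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
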