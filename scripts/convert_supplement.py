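"""Convert the per-organism workbook of reconstructed core metabolic
networks into the canonical TSV schema used by this package.

    python scripts/convert_supplement.py WORKBOOK.xlsx -o data/curated/

Writes ``reactions.tsv`` and ``organisms.tsv`` into the output directory;
the reproduction checks in the test suite pick them up from
``data/curated/``.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from coremetnet.supplement import convert_workbook


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("workbook", type=Path)
    parser.add_argument("-o", "--out", type=Path, default=Path("data/curated"))
    args = parser.parse_args()
    reactions_path, profiles_path = convert_workbook(args.workbook, args.out)
    print(f"wrote {reactions_path} and {profiles_path}")


if __name__ == "__main__":
    main()
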