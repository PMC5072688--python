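"""One-off converter: study supplementary MATLAB archives -> CSV tables.

The reference datasets ship as ``.mat`` matrices inside zip archives.  This
script converts them into the delimited text layout the test suite and the
pipelines read (``data/supplementary/*.csv``).  Run it once after unpacking
the archives:

    python scripts/import_supplementary.py --src <unpacked-dir> --dest data/supplementary

Expected inputs (file names as unpacked; adjust with --map if they differ):

- SimBoolNet trajectories (nodes x iterations)     -> s1_trajectories.csv
- ODE simulation (iterations x 112 species)        -> s2_ode.csv (constant-zero
  species dropped, apoptosis column named "Apoptosis")
- breast-cancer cell lines (observations x cols)   -> lee_bt20.csv,
  lee_mda_mb_453.csv, lee_mcf7.csv (fate column named "apoptosis")
- HT-29 time courses                               -> s4_ht29.csv
- DREAM8 per-cell-line signals                     -> s5_dream8_<line>.csv

Requires scipy (already a package dependency).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat

BOOLEAN_NODES = ("Casp8", "Casp9", "OncogenicSignature", "Casp3",
                 "CellDeath", "DNADamage", "EGFR")


def first_matrix(path: Path) -> np.ndarray:
    mat = loadmat(path)
    arrays = [v for k, v in mat.items() if not k.startswith("__")]
    if not arrays:
        raise ValueError(f"no data matrix found in {path}")
    return np.asarray(arrays[0], dtype=float)


def convert_simboolnet(src: Path, dest: Path) -> None:
    data = first_matrix(src)  # nodes x iterations
    df = pd.DataFrame(data.T, columns=list(BOOLEAN_NODES))
    df.to_csv(dest / "s1_trajectories.csv", index=False)


def convert_ode(src: Path, dest: Path, apoptosis_index: int) -> None:
    data = first_matrix(src)  # iterations x species
    keep = ~(data == 0).all(axis=0)
    cols = [f"species_{j}" for j in range(data.shape[1])]
    df = pd.DataFrame(data, columns=cols).loc[:, keep]
    df = df.rename(columns={cols[apoptosis_index]: "Apoptosis"})
    df.to_csv(dest / "s2_ode.csv", index=False)


def convert_matrix_table(src: Path, dest: Path, name: str,
                         columns=None, fate=None) -> None:
    data = first_matrix(src)  # observations x columns
    if columns is None:
        columns = [f"col_{j}" for j in range(data.shape[1])]
    df = pd.DataFrame(data, columns=columns)
    if fate is not None:
        df = df.rename(columns={columns[fate]: "apoptosis"})
    df.to_csv(dest / name, index=False)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--src", type=Path, required=True,
                        help="directory with the unpacked .mat files")
    parser.add_argument("--dest", type=Path,
                        default=Path("data/supplementary"))
    parser.add_argument("--apoptosis-index", type=int, default=None,
                        help="column index of the apoptosis species in the "
                             "ODE matrix")
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    converted = []
    for mat in sorted(args.src.glob("*.mat")):
        low = mat.stem.lower()
        if "boolnet" in low or low.startswith("s1"):
            convert_simboolnet(mat, args.dest)
        elif "celldesigner" in low or low.startswith("s2"):
            if args.apoptosis_index is None:
                parser.error("--apoptosis-index required for the ODE matrix")
            convert_ode(mat, args.dest, args.apoptosis_index)
        else:
            convert_matrix_table(mat, args.dest, f"{low}.csv")
        converted.append(mat.name)
    print(f"converted {len(converted)} archives: {', '.join(converted)}")
    print("rename/adjust fate columns as described in the module docstring "
          "before running the reference-data checks")


if __name__ == "__main__":
    main()
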