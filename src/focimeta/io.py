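"""Reading, writing, validating and converting activation-foci tables.

A foci table is the atomic dataset of coordinate-based meta-analysis: one row
per reported activation peak, holding a study identifier, the peak position in
millimetres, the stereotactic space it was reported in (Talairach or MNI), a
binary condition label (here 1 = branded, 0 = unbranded, but any two-condition
contrast works), and optionally the study's subject count.  In memory the table
is a plain :class:`pandas.DataFrame` with columns
``study_id, x, y, z, space, label[, n_subjects]``.

Two file dialects are supported: a tab-separated table with that exact header,
and the Sleuth text format used by GingerALE (``//``-prefixed study headers
followed by whitespace-separated coordinate triples).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyInputError,
    FociParseError,
    SchemaError,
    ValidationError,
    ConfigError,
)

SPACES = ("MNI", "TAL")
COORD_BOUND = 120.0  # liberal validity envelope in mm, either sign
REQUIRED_COLUMNS = ["study_id", "x", "y", "z", "space", "label"]
OPTIONAL_COLUMNS = ["n_subjects"]

# Lancaster et al. (2007), "Bias between MNI and Talairach coordinates
# analyzed using the ICBM-152 brain template": best-fit affines mapping ICBM/MNI
# coordinates to Talairach-1988 space, one fit per normalization family.
# The TAL->MNI direction used here is the matrix inverse, exactly as distributed
# in BrainMap's tal2icbm converters.
ICBM_SPM2TAL = np.array(
    [
        [0.9254, 0.0024, -0.0118, -1.0207],
        [-0.0048, 0.9316, -0.0871, -1.7667],
        [0.0152, 0.0883, 0.8924, 4.0926],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
ICBM_FSL2TAL = np.array(
    [
        [0.9464, 0.0034, -0.0026, -1.0680],
        [-0.0083, 0.9479, -0.0580, -1.0239],
        [0.0053, 0.0617, 0.9010, 3.1905],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

TAL_TO_MNI_AFFINES = {
    "lancaster_spm": np.linalg.inv(ICBM_SPM2TAL),
    "lancaster_fsl": np.linalg.inv(ICBM_FSL2TAL),
}


def validate_foci(foci: pd.DataFrame) -> pd.DataFrame:
    """Check domain invariants on a foci table and return it unchanged.

    Raises :class:`ValidationError` on the first violated invariant:
    finite coordinates within +/-120 mm, label in {0, 1}, known space tag,
    n_subjects >= 1 where present.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in foci.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(foci) == 0:
        raise EmptyInputError("foci table is empty")
    coords = foci[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValidationError("non-finite coordinate present")
    if (np.abs(coords) > COORD_BOUND).any():
        bad = foci.index[(np.abs(coords) > COORD_BOUND).any(axis=1)][0]
        raise ValidationError(
            f"coordinate outside +/-{COORD_BOUND:g} mm at row {bad}"
        )
    if not foci["label"].isin([0, 1]).all():
        raise ValidationError("label column must be binary (0 or 1)")
    if not foci["space"].isin(SPACES).all():
        bad = sorted(set(foci["space"]) - set(SPACES))
        raise ValidationError(f"unknown space tag(s): {bad}")
    if "n_subjects" in foci.columns:
        n = foci["n_subjects"].dropna()
        if (n < 1).any():
            raise ValidationError("n_subjects must be >= 1 where present")
    return foci


def _read_tsv(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file")
    header = lines[0].split("\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    col = {name: i for i, name in enumerate(header)}
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < len(REQUIRED_COLUMNS):
            raise FociParseError(f"expected >= {len(REQUIRED_COLUMNS)} fields", lineno)
        rec = {}
        rec["study_id"] = parts[col["study_id"]].strip()
        for axis in ("x", "y", "z"):
            raw = parts[col[axis]].strip()
            try:
                rec[axis] = float(raw)
            except ValueError:
                raise FociParseError(f"non-numeric {axis} value {raw!r}", lineno) from None
        rec["space"] = parts[col["space"]].strip()
        raw_label = parts[col["label"]].strip()
        try:
            rec["label"] = int(raw_label)
        except ValueError:
            raise FociParseError(f"non-integer label {raw_label!r}", lineno) from None
        if "n_subjects" in col and len(parts) > col["n_subjects"]:
            raw_n = parts[col["n_subjects"]].strip()
            if raw_n:
                try:
                    rec["n_subjects"] = int(raw_n)
                except ValueError:
                    raise FociParseError(
                        f"non-integer n_subjects {raw_n!r}", lineno
                    ) from None
        rows.append(rec)
    df = pd.DataFrame(rows)
    if "n_subjects" in df.columns:
        df["n_subjects"] = df["n_subjects"].astype("Int64")
    return df


_SLEUTH_REFERENCE = re.compile(r"reference\s*=\s*(\w+)", re.IGNORECASE)
_SLEUTH_SUBJECTS = re.compile(r"subjects\s*=\s*(\d+)", re.IGNORECASE)


def _read_sleuth(path: Path, label: int) -> pd.DataFrame:
    """Parse a Sleuth text foci file.

    ``// Reference=MNI`` (or Talairach) sets the space for the whole file;
    runs of ``//`` comment lines delimit studies, with an optional
    ``// Subjects=N``; each following non-comment line is one x y z triple.
    """
    space = "MNI"
    rows: list[dict] = []
    study_name: str | None = None
    study_subjects: int | None = None
    in_header = False
    n_anonymous = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                in_header = False
                continue
            if stripped.startswith("//"):
                body = stripped[2:].strip()
                m = _SLEUTH_REFERENCE.search(body)
                if m:
                    tag = m.group(1).upper()
                    if tag.startswith("TAL"):
                        space = "TAL"
                    elif tag == "MNI":
                        space = "MNI"
                    else:
                        raise ValidationError(f"line {lineno}: unknown reference space {tag!r}")
                    continue
                if not in_header:
                    # first comment line of a new study block
                    in_header = True
                    study_name = None
                    study_subjects = None
                m2 = _SLEUTH_SUBJECTS.search(body)
                if m2:
                    study_subjects = int(m2.group(1))
                elif body and study_name is None:
                    study_name = body
                continue
            in_header = False
            if study_name is None:
                n_anonymous += 1
                study_name = f"study_{n_anonymous}"
            parts = stripped.split()
            if len(parts) != 3:
                raise FociParseError("expected an 'x y z' coordinate triple", lineno)
            try:
                x, y, z = (float(p) for p in parts)
            except ValueError:
                raise FociParseError(f"non-numeric coordinate in {stripped!r}", lineno) from None
            rec = {"study_id": study_name, "x": x, "y": y, "z": z,
                   "space": space, "label": label}
            if study_subjects is not None:
                rec["n_subjects"] = study_subjects
            rows.append(rec)
    df = pd.DataFrame(rows)
    if "n_subjects" in df.columns:
        df["n_subjects"] = df["n_subjects"].astype("Int64")
    return df


def read_foci_table(path, dialect: str = "tsv", label: int | None = None) -> pd.DataFrame:
    """Read and validate a foci table.

    Parameters
    ----------
    path : path-like
        Input file.
    dialect : {'tsv', 'sleuth'}
        ``tsv`` expects a header ``study_id,x,y,z,space,label[,n_subjects]``
        (tab-separated).  ``sleuth`` is the GingerALE text format and carries
        no condition label, so ``label`` must be given.
    label : int, optional
        Condition label applied to every focus of a Sleuth file.

    Returns
    -------
    pandas.DataFrame
        Validated foci table, row order preserved.  The provenance (the file
        path) is recorded in ``df.attrs['provenance']``.
    """
    path = Path(path)
    if dialect == "tsv":
        df = _read_tsv(path)
    elif dialect == "sleuth":
        if label is None:
            raise ConfigError("the sleuth dialect carries no labels; pass label=0 or 1")
        df = _read_sleuth(path, int(label))
    else:
        raise ConfigError(f"unknown dialect {dialect!r}")
    validate_foci(df)
    df.attrs["provenance"] = str(path)
    return df.reset_index(drop=True)


def write_foci_table(foci: pd.DataFrame, path, dialect: str = "tsv") -> None:
    """Write a foci table in either supported dialect (UTF-8, decimal point)."""
    path = Path(path)
    if dialect == "tsv":
        cols = list(REQUIRED_COLUMNS)
        if "n_subjects" in foci.columns:
            cols.append("n_subjects")
        foci.to_csv(path, sep="\t", index=False, columns=cols)
    elif dialect == "sleuth":
        with open(path, "w", encoding="utf-8") as fh:
            space = foci["space"].iloc[0] if len(foci) else "MNI"
            if not (foci["space"] == space).all():
                raise ValidationError("sleuth files hold a single reference space")
            fh.write(f"// Reference={'Talairach' if space == 'TAL' else 'MNI'}\n")
            for study, block in foci.groupby("study_id", sort=False):
                fh.write(f"// {study}\n")
                if "n_subjects" in block.columns and block["n_subjects"].notna().all():
                    fh.write(f"// Subjects={int(block['n_subjects'].iloc[0])}\n")
                for _, row in block.iterrows():
                    fh.write(f"{row.x:.17g}\t{row.y:.17g}\t{row.z:.17g}\n")
                fh.write("\n")
    else:
        raise ConfigError(f"unknown dialect {dialect!r}")


def convert_to_mni(foci: pd.DataFrame, variant: str = "lancaster_spm") -> pd.DataFrame:
    """Map Talairach-tagged foci into MNI space with a published affine.

    MNI-tagged rows pass through unchanged; TAL-tagged rows are transformed by
    the selected Lancaster tal2icbm affine (the inverse of the published
    icbm2tal fit; ``lancaster_spm`` by default, ``lancaster_fsl`` for the
    FSL-flavour fit).  The returned table is tagged MNI throughout.
    """
    if variant not in TAL_TO_MNI_AFFINES:
        raise ConfigError(
            f"unknown TAL->MNI variant {variant!r}; "
            f"available: {sorted(TAL_TO_MNI_AFFINES)}"
        )
    validate_foci(foci)
    out = foci.copy()
    tal = out["space"] == "TAL"
    if tal.any():
        pts = out.loc[tal, ["x", "y", "z"]].to_numpy(dtype=float)
        hom = np.c_[pts, np.ones(len(pts))]
        mapped = hom @ TAL_TO_MNI_AFFINES[variant].T
        out.loc[tal, ["x", "y", "z"]] = mapped[:, :3]
    out["space"] = "MNI"
    return out


def summarize(foci: pd.DataFrame) -> pd.DataFrame:
    """Per-axis descriptive statistics for the whole table and each label.

    Returns one row per (subset, axis) with n, mean, sd (sample, n-1
    convention; 0 and flagged degenerate when n = 1), median, min and max.
    """
    validate_foci(foci)
    subsets = {"all": foci, "label_1": foci[foci["label"] == 1],
               "label_0": foci[foci["label"] == 0]}
    rows = []
    for name, sub in subsets.items():
        for axis in ("x", "y", "z"):
            v = sub[axis].to_numpy(dtype=float)
            n = len(v)
            degenerate = n == 1
            rows.append({
                "subset": name, "axis": axis, "n": n,
                "mean": v.mean() if n else np.nan,
                "sd": 0.0 if degenerate else (v.std(ddof=1) if n else np.nan),
                "median": float(np.median(v)) if n else np.nan,
                "min": v.min() if n else np.nan,
                "max": v.max() if n else np.nan,
                "degenerate_sd": degenerate,
            })
    return pd.DataFrame(rows)
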