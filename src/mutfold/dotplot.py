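"""File interop: ViennaRNA-dialect PostScript dot plots and TSV tables.

The dot-plot dialect is the one RNAplfold/RNAfold emit: a ``/sequence``
record holding the RNA, and data lines ``i j v ubox`` where ``v`` encodes
the *square root* of the pair probability (historically the dot radius).
``lbox`` (single-structure) entries are ignored with a warning -- this is
an ensemble-only tool.  Exported probabilities below 1e-7 are dropped to
bound file size; in-memory values are never truncated.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .fold import AccessibilityProfile, BasePairMatrix, FoldingParams
from .sequences import RnaSequence, validate_sequence

__all__ = [
    "DotPlotError",
    "read_ps_dotplot",
    "write_ps_dotplot",
    "write_tsv_outputs",
    "read_pairs_tsv",
    "read_accessibility_tsv",
]

EXPORT_TRUNCATION = 1e-7


class DotPlotError(ValueError):
    """Raised for malformed dot-plot files."""


_UBOX_RE = re.compile(r"^(\d+)\s+(\d+)\s+([0-9.eE+-]+)\s+ubox$")
_LBOX_RE = re.compile(r"^(\d+)\s+(\d+)\s+([0-9.eE+-]+)\s+lbox$")


def read_ps_dotplot(path) -> tuple:
    """Parse a PostScript dot plot into (sequence, BasePairMatrix).

    P(i,j) = v^2 for each ``i j v ubox`` line, symmetrized; entries absent
    from the file are zero; n comes from the embedded sequence record.
    """
    path = Path(path)
    text = path.read_text()

    seq_match = re.search(r"/sequence\s*\{\s*\((.*?)\)\s*\}\s*def", text, re.DOTALL)
    if seq_match is None:
        raise DotPlotError(f"{path}: missing /sequence record")
    raw_seq = seq_match.group(1).replace("\\", "").strip()
    seq = validate_sequence(raw_seq, id=path.stem)
    n = seq.n

    P = np.zeros((n, n))
    lbox_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if _LBOX_RE.match(stripped):
            lbox_seen = True
            continue
        m = _UBOX_RE.match(stripped)
        if m is None:
            if stripped.endswith("ubox") and stripped[:1].isdigit():
                raise DotPlotError(f"{path}:{lineno}: malformed ubox line {line!r}")
            continue
        i, j, v = int(m.group(1)), int(m.group(2)), float(m.group(3))
        if not (1 <= i <= n and 1 <= j <= n and i != j):
            raise DotPlotError(
                f"{path}:{lineno}: pair ({i},{j}) out of range for n={n}"
            )
        if not 0.0 <= v <= 1.0 + 1e-9:
            raise DotPlotError(
                f"{path}:{lineno}: value {v} outside [0,1] "
                "(expected sqrt of a probability)"
            )
        P[i - 1, j - 1] = v * v
        P[j - 1, i - 1] = v * v
    if lbox_seen:
        warnings.warn(
            f"{path}: lbox (single-structure) entries ignored; this tool "
            "works on ensemble probabilities only",
            stacklevel=2,
        )
    matrix = BasePairMatrix(n=n, P=P, params=FoldingParams(), model_id="dotplot-file")
    return seq, matrix


def write_ps_dotplot(matrix: BasePairMatrix, seq: RnaSequence, path) -> Path:
    """Write a matrix as a dot-plot file readable by :func:`read_ps_dotplot`."""
    if matrix.n != seq.n:
        raise ValueError(f"matrix n={matrix.n} != sequence n={seq.n}")
    path = Path(path)
    lines = [
        "%!PS-Adobe-3.0 EPSF-3.0",
        "%%Title: RNA pair probability dot plot",
        "%%Creator: mutfold",
        "% Dialect note: data lines 'i j v ubox' encode P(i,j) = v^2",
        "% (ViennaRNA dot-plot convention); 1-based positions.",
        "/sequence { (\\",
        f"{seq.residues}\\",
        ") } def",
        "/ubox {} def",
        "/lbox {} def",
    ]
    iu = np.triu_indices(matrix.n, k=1)
    for i, j in zip(*iu):
        p = matrix.P[i, j]
        if p < EXPORT_TRUNCATION:
            continue
        lines.append(f"{i + 1} {j + 1} {np.sqrt(p):.9f} ubox")
    lines.append("showpage")
    path.write_text("\n".join(lines) + "\n")
    return path


# --- TSV / JSON outputs ----------------------------------------------------

_PAIRS_HEADER = (
    "# pair-probability table: i, j are 1-based, i < j\n"
    "# delta = p_mut - p_wt (positive = pair strengthened by the mutation)\n"
)
_ACC_HEADER = (
    "# accessibility table: pos is 1-based\n"
    "# acc_delta = pu_wt - pu_mut (negative = more accessible in the mutant)\n"
)


def write_tsv_outputs(diff, wt_acc, mut_acc, report, out_dir) -> dict:
    """Write long-format TSVs plus the impact-report JSON into ``out_dir``.

    ``diff`` is a :class:`~mutfold.diff.DiffResult`; ``report`` may be None
    (dot-plot backend without refolding).  Returns a name -> path dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = diff.n

    def trunc(x):
        x = np.where(np.abs(x) < EXPORT_TRUNCATION, 0.0, x)
        return x

    iu = np.triu_indices(n, k=1)
    p_wt = trunc(diff.p_wt[iu])
    p_mut = trunc(diff.p_mut[iu])
    delta = trunc(diff.delta[iu])
    keep = (p_wt != 0) | (p_mut != 0) | (delta != 0)
    pairs = pd.DataFrame(
        {
            "i": iu[0][keep] + 1,
            "j": iu[1][keep] + 1,
            "p_wt": p_wt[keep],
            "p_mut": p_mut[keep],
            "delta": delta[keep],
        }
    )
    pairs_path = out_dir / "pairs.tsv"
    with open(pairs_path, "w") as fh:
        fh.write(_PAIRS_HEADER)
        pairs.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    acc = pd.DataFrame(
        {
            "pos": np.arange(1, n + 1),
            "pu_wt": diff.pu_wt,
            "pu_mut": diff.pu_mut,
            "acc_delta": diff.acc_delta,
        }
    )
    acc_path = out_dir / "accessibility.tsv"
    with open(acc_path, "w") as fh:
        fh.write(_ACC_HEADER)
        acc.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    paths = {"pairs": pairs_path, "accessibility": acc_path}
    if report is not None:
        from . import __version__

        payload = report.to_dict() if hasattr(report, "to_dict") else report
        payload = {"tool": "mutfold", "version": __version__, **payload}
        impact_path = out_dir / "impact.json"
        impact_path.write_text(json.dumps(payload, indent=2) + "\n")
        paths["impact"] = impact_path
    return paths


def read_pairs_tsv(path, n: int):
    """Reconstruct (P_wt, P_mut, delta) matrices from pairs.tsv."""
    df = pd.read_csv(path, sep="\t", comment="#")
    P_wt = np.zeros((n, n))
    P_mut = np.zeros((n, n))
    delta = np.zeros((n, n))
    for row in df.itertuples(index=False):
        i, j = int(row.i) - 1, int(row.j) - 1
        for M, v in ((P_wt, row.p_wt), (P_mut, row.p_mut), (delta, row.delta)):
            M[i, j] = v
            M[j, i] = v
    return P_wt, P_mut, delta


def read_accessibility_tsv(path):
    """Reconstruct (pu_wt, pu_mut, acc_delta) arrays from accessibility.tsv."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return (
        df["pu_wt"].to_numpy(),
        df["pu_mut"].to_numpy(),
        df["acc_delta"].to_numpy(),
    )
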