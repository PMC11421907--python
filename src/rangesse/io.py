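"""Readers, writers and cross-validation for trees and tip-range tables.

Range tables are delimited text (TSV by default, comma accepted) with a
header and one row per tip, in either of two dialects:

* a ``range`` column of delimiter-separated area labels
  (``sp1<TAB>Borneo,Sumatra``), or
* one 0/1 presence column per area, in the area order of the analysis.

The dialect is auto-detected from the header; if a table satisfies both, the
0/1 matrix reading wins and a notice is logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .statespace import RangeState, StateSpace, parse_range
from .trees import IndexedTree

logger = logging.getLogger("rangesse")

__all__ = [
    "read_ranges",
    "write_ranges",
    "validate_tips",
    "write_marginals",
    "annotated_newick",
    "write_richness",
    "write_run_record",
]


def _read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_ranges(path, space: StateSpace) -> dict[str, RangeState]:
    """Read a tip-range table in either dialect into a tip -> range map."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a tip column plus range information")
    tip_col = df.columns[0]
    has_matrix = all(lab in df.columns for lab in space.labels)
    has_list = "range" in df.columns
    if has_matrix and has_list:
        logger.info("%s: both range-table dialects present; using the 0/1 matrix", path)
    if not has_matrix and not has_list:
        raise ValueError(
            f"{path}: need either a 'range' column or one 0/1 column per area "
            f"({', '.join(space.labels)})"
        )
    dup = df[tip_col][df[tip_col].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate tip rows: {', '.join(dup.tolist()[:5])}")
    out: dict[str, RangeState] = {}
    for _, row in df.iterrows():
        tip = str(row[tip_col])
        try:
            if has_matrix:
                bits = 0
                for a in space.areas:
                    flag = str(row[a.label]).strip()
                    if flag not in ("0", "1"):
                        raise ValueError(f"presence flag must be 0 or 1, got {flag!r}")
                    bits |= (flag == "1") << a.index
                if bits == 0:
                    raise ValueError("presence vector is all zeros: empty range")
                out[tip] = space._check(RangeState(bits))
            else:
                out[tip] = parse_range(str(row["range"]), space)
        except ValueError as err:
            raise ValueError(f"{path}: tip {tip!r}: {err}") from None
    return out


def write_ranges(tip_ranges: Mapping[str, RangeState], space: StateSpace, path,
                 dialect: str = "labels") -> None:
    rows = []
    for tip, state in tip_ranges.items():
        if dialect == "labels":
            rows.append({"tip": tip, "range": space.format_state(state, sep=",")})
        else:
            row = {"tip": tip}
            row.update({a.label: int(state.contains(a.index)) for a in space.areas})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def validate_tips(itree: IndexedTree, tip_ranges: Mapping[str, RangeState]) -> None:
    """Cross-check tree tips against the range table; report every mismatch."""
    tree_tips = set(itree.tip_index)
    table_tips = set(tip_ranges)
    problems = []
    if tree_tips - table_tips:
        problems.append("tips without ranges: " + ", ".join(sorted(tree_tips - table_tips)[:10]))
    if table_tips - tree_tips:
        problems.append("range rows not in tree: " + ", ".join(sorted(table_tips - tree_tips)[:10]))
    if problems:
        raise ValueError("; ".join(problems))


def write_marginals(marginals, path) -> None:
    marginals.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def annotated_newick(marginals, path=None) -> str:
    """Newick of the analysed tree with top-3 states per node as comments."""
    itree = marginals.itree
    space = marginals.space

    def fmt(v: int) -> str:
        p = marginals.probs[v]
        top = np.argsort(p)[::-1][:3]
        body = ",".join(f"{space.format_state(space.states[i])}:{p[i]:.3f}" for i in top)
        return f"[&states={{{body}}}]"

    def rec(v: int) -> str:
        if itree.is_tip(v):
            return f"{itree.label_of(v)}{fmt(v)}:{itree.branch_lengths[v]:.8g}"
        sub = f"({rec(int(itree.left[v]))},{rec(int(itree.right[v]))})node{v}{fmt(v)}"
        if v == itree.root:
            return sub
        return f"{sub}:{itree.branch_lengths[v]:.8g}"

    text = rec(itree.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def write_richness(profile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_run_record(path, *, version: str, config: dict, seed: int | None,
                     wall_clock_s: float, stages: dict[str, str]) -> None:
    """Reproducibility record emitted for every command-line invocation."""
    record = {
        "tool": "rangesse",
        "version": version,
        "seed": seed,
        "wall_clock_s": round(wall_clock_s, 3),
        "config": config,
        "stages": stages,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
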