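"""Benchmarking call sets against a support/truth set.

Given merged loci (each carrying the set of callers and sources that
discovered it) and a support set of locus ids (e.g. the loci corroborated
by hybrid assembly, or a simulated truth match), this module computes:

* per-caller false-discovery rate and sensitivity
  (FDR = unsupported/total called; sensitivity = supported/|support set|),
* the symmetric source-pair support matrix (off-diagonal cell (i, j):
  loci discovered by both sources; diagonal (i, i): loci discovered by
  exactly that one source),
* log-spaced size histograms per canonical type.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import ConsensvError, Locus, SVType

EVAL_COLUMNS = ["caller", "total_called", "supported", "unsupported", "fdr", "sensitivity"]


def evaluate_callers(
    loci: Sequence[Locus], support_set: Iterable[str]
) -> pd.DataFrame:
    """Per-caller FDR and sensitivity against a support set of locus ids.

    A caller's total is the number of loci whose member calls include that
    caller; its supported count is the intersection with the support set.
    The sensitivity denominator is the full support set as supplied (and
    is echoed in ``df.attrs["support_set_size"]``); with an empty support
    set sensitivity is undefined (NaN) and flagged in
    ``df.attrs["sensitivity_defined"]``.
    """
    support = set(support_set)
    unknown = support - {l.id for l in loci}
    if unknown:
        raise ConsensvError(
            f"support set contains {len(unknown)} unknown locus ids (e.g. {sorted(unknown)[:3]})"
        )
    per_caller: dict[str, list[int]] = {}
    for locus in loci:
        hit = locus.id in support
        for caller in locus.callers:
            tot_sup = per_caller.setdefault(caller, [0, 0])
            tot_sup[0] += 1
            tot_sup[1] += int(hit)
    denom = len(support)
    rows = []
    for caller in sorted(per_caller):
        total, supported = per_caller[caller]
        unsupported = total - supported
        rows.append(
            {
                "caller": caller,
                "total_called": total,
                "supported": supported,
                "unsupported": unsupported,
                "fdr": unsupported / total if total else 0.0,
                "sensitivity": supported / denom if denom else float("nan"),
            }
        )
    df = pd.DataFrame(rows, columns=EVAL_COLUMNS)
    df.attrs["support_set_size"] = denom
    df.attrs["sensitivity_defined"] = denom > 0
    return df


def source_pair_matrix(loci: Sequence[Locus]) -> pd.DataFrame:
    """Symmetric source-pair support matrix.

    Cell (i, j), i != j: number of loci whose source set contains both i
    and j.  Cell (i, i): number of loci whose source set is exactly {i}.
    """
    sources = sorted({s for l in loci for s in l.sources})
    mat = pd.DataFrame(0, index=sources, columns=sources, dtype=int)
    for locus in loci:
        ss = sorted(locus.sources)
        if len(ss) == 1:
            mat.loc[ss[0], ss[0]] += 1
            continue
        for i, a in enumerate(ss):
            for b in ss[i + 1 :]:
                mat.loc[a, b] += 1
                mat.loc[b, a] += 1
    return mat


def size_histogram(
    loci: Sequence[Locus],
    bins: int | Sequence[float] = 20,
    min_size: int = 100,
    max_size: int = 100_000,
) -> pd.DataFrame:
    """Per-type counts over log-spaced size bins.

    Size bounds are strict: only loci with min_size < size < max_size are
    counted.  Returns one row per bin with per-type columns plus bin
    edges; ``df.attrs["totals"]`` holds the per-type totals.
    """
    if isinstance(bins, int):
        edges = np.logspace(np.log10(min_size), np.log10(max_size), bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    table: dict[str, np.ndarray] = {}
    totals: dict[str, int] = {}
    for svtype in SVType:
        sizes = [
            l.size for l in loci if l.svtype == svtype and min_size < l.size < max_size
        ]
        counts, _ = np.histogram(sizes, bins=edges)
        table[svtype.value] = counts
        totals[svtype.value] = int(len(sizes))
    df = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            **{k: v for k, v in table.items()},
        }
    )
    df.attrs["totals"] = totals
    return df


def write_eval_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write the per-caller table; the sensitivity denominator is echoed
    in a header comment so the basis of the column is never ambiguous."""
    with open(path, "w") as fh:
        fh.write(f"#support_set_size={df.attrs.get('support_set_size', 'NA')}\n")
        fh.write("#" + "\t".join(EVAL_COLUMNS) + "\n")
        for _, row in df.iterrows():
            fh.write(
                f"{row['caller']}\t{row['total_called']}\t{row['supported']}\t"
                f"{row['unsupported']}\t{row['fdr'] * 100:.2f}%\t"
                + (
                    f"{row['sensitivity'] * 100:.2f}%\n"
                    if pd.notna(row["sensitivity"])
                    else "NA\n"
                )
            )


def write_matrix_tsv(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t", index_label="source")


def write_histogram_tsv(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        totals = df.attrs.get("totals", {})
        fh.write(
            "#totals\t" + "\t".join(f"{k}={v}" for k, v in sorted(totals.items())) + "\n"
        )
        df.to_csv(fh, sep="\t", index=False, float_format="%.1f")
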