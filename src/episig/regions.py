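"""Differentially methylated region (DMR) detection.

Two rules operate on genomically sorted probes:

* :func:`find_dmrs` — significance-based calling over the full
  differential table. Probes on a chromosome are chained into candidate
  regions while consecutive gaps stay within a window (1 kb default);
  candidates need at least ``min_cpgs`` probes and a mean |delta-beta| of
  at least ``min_delta`` (5%). Each candidate gets a Fisher combined
  probability (X^2 = -2 sum ln p_i on 2k df), Benjamini-Hochberg adjusted
  across candidates; regions with adjusted p below ``alpha`` are reported.
* :func:`find_signature_regions` — the descriptive adjacency rule over
  episignature probes only: runs of three or more signature probes in
  direct vicinity with a consistent direction of effect, no test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .signature import Episignature

_CHROMOSOMES = {f"chr{i}" for i in range(1, 23)} | {"chrX", "chrY", "chrM"}


@dataclass
class Dmr:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    probe_ids: list[str]
    mean_delta_beta: float
    combined_p: float = np.nan
    adjusted_p: float = np.nan
    direction_consistent: bool = False

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def _located(probe_ids: pd.Index, manifest: pd.DataFrame) -> pd.DataFrame:
    missing = probe_ids.difference(manifest.index)
    if len(missing) > 0:
        raise InputError(f"probes missing from manifest: {list(missing[:5])}")
    loc = manifest.loc[probe_ids, ["chromosome", "position"]].copy()
    unknown = set(loc["chromosome"]) - _CHROMOSOMES
    if unknown:
        raise InputError(f"unknown chromosomes in manifest: {sorted(unknown)[:5]}")
    return loc


def _chained_runs(positions: np.ndarray, window: int) -> list[slice]:
    """Maximal runs of sorted positions with consecutive gaps <= window."""
    if positions.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > window) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [positions.size]])
    return [slice(a, b) for a, b in zip(starts, ends)]


def fisher_combined_p(p_values: np.ndarray) -> tuple[float, float]:
    """Fisher's combined probability: returns (X^2, p) on 2k df."""
    p = np.asarray(p_values, float)
    x2 = float(-2.0 * np.log(p).sum())
    return x2, float(stats.chi2.sf(x2, 2 * p.size))


def find_dmrs(
    dmp: pd.DataFrame,
    manifest: pd.DataFrame,
    min_cpgs: int = 3,
    window: int = 1000,
    min_delta: float = 0.05,
    alpha: float = 0.01,
    span_rule: bool = False,
) -> list[Dmr]:
    """Significance-based DMRs from a differential table.

    ``span_rule`` switches the 1 kb criterion from consecutive-gap chaining
    (default) to a total-span limit per region.
    """
    loc = _located(dmp.index, manifest)
    candidates: list[Dmr] = []
    for chrom, sub in loc.groupby("chromosome", sort=True):
        sub = sub.sort_index().sort_values("position", kind="mergesort")
        pos = sub["position"].to_numpy(np.int64)
        for run in _chained_runs(pos, window):
            ids = list(sub.index[run])
            if len(ids) < min_cpgs:
                continue
            if span_rule and pos[run][-1] - pos[run][0] > window:
                continue
            delta = dmp.loc[ids, "delta_beta"].to_numpy(float)
            mean_delta = float(delta.mean())
            if abs(mean_delta) < min_delta:
                continue
            x2, p_comb = fisher_combined_p(dmp.loc[ids, "p"].to_numpy(float))
            candidates.append(
                Dmr(
                    chromosome=str(chrom),
                    start=int(pos[run][0]),
                    end=int(pos[run][-1]),
                    probe_ids=ids,
                    mean_delta_beta=mean_delta,
                    combined_p=p_comb,
                    direction_consistent=bool(
                        (delta > 0).all() or (delta < 0).all()
                    ),
                )
            )
    if not candidates:
        return []
    _, adj, _, _ = multipletests(
        [c.combined_p for c in candidates], method="fdr_bh"
    )
    out = []
    for c, q in zip(candidates, adj):
        c.adjusted_p = float(q)
        if q < alpha:
            out.append(c)
    return out


def find_signature_regions(
    episignature: Episignature,
    dmp: pd.DataFrame,
    manifest: pd.DataFrame,
    window: int = 1000,
) -> list[Dmr]:
    """Adjacency rule over signature probes: >2 nearby probes, same direction.

    Runs of at least three signature probes whose consecutive gaps are
    within ``window`` and whose delta-beta signs agree; purely descriptive,
    no significance test.
    """
    probes = pd.Index(episignature.probe_ids)
    loc = _located(probes, manifest)
    delta = dmp.loc[probes, "delta_beta"]
    regions: list[Dmr] = []
    for chrom, sub in loc.groupby("chromosome", sort=True):
        sub = sub.sort_index().sort_values("position", kind="mergesort")
        pos = sub["position"].to_numpy(np.int64)
        signs = np.sign(delta.loc[sub.index].to_numpy(float))
        # break runs on the window AND on direction changes
        gap_break = np.diff(pos) > window
        sign_break = signs[1:] != signs[:-1]
        breaks = np.flatnonzero(gap_break | sign_break) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [pos.size]])
        for a, b in zip(starts, ends):
            if b - a < 3:
                continue
            ids = list(sub.index[a:b])
            regions.append(
                Dmr(
                    chromosome=str(chrom),
                    start=int(pos[a]),
                    end=int(pos[b - 1]),
                    probe_ids=ids,
                    mean_delta_beta=float(delta.loc[ids].mean()),
                    direction_consistent=True,
                )
            )
    return regions


def dmrs_to_frame(dmrs: list[Dmr]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": d.chromosome,
                "start": d.start,
                "end": d.end,
                "n_probes": d.n_probes,
                "mean_delta_beta": d.mean_delta_beta,
                "combined_p": d.combined_p,
                "adjusted_p": d.adjusted_p,
                "direction_consistent": d.direction_consistent,
                "probe_ids": ",".join(d.probe_ids),
            }
            for d in dmrs
        ]
    )


def write_bed(dmrs: list[Dmr], path: str | Path) -> None:
    """Write regions as BED (0-based half-open, converted from 1-based)."""
    lines = [
        f"{d.chromosome}\t{d.start - 1}\t{d.end}\tDMR_{i + 1}\t{d.n_probes}"
        for i, d in enumerate(dmrs)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
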