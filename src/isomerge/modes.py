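"""Execution modes: dendrogram-only, analysis, synthesis, combination, pruning.

A run lives in a working directory.  Analysis writes the bookkeeping files
(mtz_names.dat, CLUSTERS.txt, FINAL_list_of_files.dat) plus a state record
(analysis_state.json) that synthesis/combination reload; the dendrogram is
rebuilt deterministically from the stored inputs rather than serialised.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO

import numpy as np

from . import plots
from .cellclust import Dendrogram, build_dendrogram, cut_tree, write_clusters_file
from .reflio import (
    FinalListEntry,
    KeywordSet,
    UnmergedDataset,
    gather_inputs,
    read_dataset,
    write_final_list,
)
from .resest import analysis_pass
from .scalemerge import MergeResult, MergeStats, merge_group

log = logging.getLogger(__name__)

__all__ = [
    "CombinationSpec",
    "PruneCycle",
    "AnalysisState",
    "parse_keywords",
    "parse_combination",
    "mode_dendrogram_only",
    "mode_analysis",
    "mode_synthesis",
    "mode_combination",
    "mode_pruning",
    "mode_graphics",
]

STATE_FILE = "analysis_state.json"
STATS_FILE = "MERGING_STATISTICS.info"

_KEYWORD_FLOATS = {
    "RADFRAC": "radfrac",
    "ISIGI": "isigi",
    "TOLERANCE": "tolerance",
    "COMPLETENESS": "completeness_target",
    "PRUNEFRAC": "prune_fraction",
}
_KEYWORD_INTS = {"MAXCYCLES": "max_prune_cycles", "SEED": "seed"}


def parse_keywords(stream: TextIO | str | None) -> KeywordSet:
    """Parse a keyword stream, one keyword per line; empty input = defaults.

    Recognised: RESOLUTION HIGH x, RESOLUTION LOW x, TOLERANCE n, RADFRAC x,
    ISIGI x, COMPLETENESS x, MAXCYCLES n, PRUNEFRAC x, SEED n.  Unknown
    keywords produce a warning and are ignored.
    """
    values: dict = {}
    if stream is None:
        return KeywordSet()
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        key = parts[0].upper()
        try:
            if key == "RESOLUTION" and len(parts) >= 3:
                which = parts[1].upper()
                if which == "HIGH":
                    values["resolution_high"] = float(parts[2])
                elif which == "LOW":
                    values["resolution_low"] = float(parts[2])
                else:
                    raise ValueError(line)
            elif key in _KEYWORD_FLOATS and len(parts) >= 2:
                values[_KEYWORD_FLOATS[key]] = float(parts[1])
            elif key in _KEYWORD_INTS and len(parts) >= 2:
                values[_KEYWORD_INTS[key]] = int(parts[1])
            else:
                warnings.warn(f"ignoring unknown keyword line: {line!r}", UserWarning)
        except ValueError:
            warnings.warn(f"ignoring malformed keyword line: {line!r}", UserWarning)
    return KeywordSet(**values)


# ---------------------------------------------------------------------------
# analysis state


@dataclass
class AnalysisState:
    """Everything synthesis/combination need from a previous analysis run."""

    paths: list[str]
    entries: list[FinalListEntry]
    workdir: str

    def save(self) -> None:
        payload = {
            "paths": self.paths,
            "entries": [dataclasses.asdict(e) for e in self.entries],
        }
        with open(Path(self.workdir) / STATE_FILE, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, workdir: str | Path) -> "AnalysisState":
        path = Path(workdir) / STATE_FILE
        if not path.is_file():
            raise FileNotFoundError(
                f"no analysis state in {workdir}; run the analysis mode first"
            )
        with open(path) as fh:
            payload = json.load(fh)
        entries = [FinalListEntry(**e) for e in payload["entries"]]
        return cls(paths=payload["paths"], entries=entries, workdir=str(workdir))

    def load_datasets(self, apply_cutoffs: bool = True) -> list[UnmergedDataset]:
        """Re-read the input files; truncate to the accepted image ranges."""
        by_serial = {e.serial: e for e in self.entries}
        datasets = []
        for serial, p in enumerate(self.paths, 1):
            ds = read_dataset(p)
            ds.serial = serial
            entry = by_serial.get(serial)
            if apply_cutoffs and entry is not None and entry.effective_cutoff < ds.last_image:
                ds = ds.truncated(last=entry.effective_cutoff)
            datasets.append(ds)
        return datasets


# ---------------------------------------------------------------------------
# dendrogram-only and analysis


def mode_dendrogram_only(
    target: str | Path, workdir: str | Path = ".", keywords: KeywordSet | None = None
) -> tuple[Dendrogram, list[UnmergedDataset]]:
    """Quick clustering: mtz_names.dat, CLUSTERS.txt and the dendrogram plot."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    datasets = gather_inputs(target, workdir=workdir)
    if len(datasets) < 2:
        raise ValueError("clustering needs at least 2 datasets")
    dendro = build_dendrogram(datasets)
    write_clusters_file(dendro, workdir / "CLUSTERS.txt")
    plots.plot_dendrogram(dendro, path=workdir / "tree.png")
    return dendro, datasets


def mode_analysis(
    target: str | Path, workdir: str | Path = ".", keywords: KeywordSet | None = None
) -> tuple[Dendrogram, list[FinalListEntry]]:
    """Clustering plus damage cutoffs and resolution estimates per dataset."""
    keywords = keywords or KeywordSet()
    workdir = Path(workdir)
    dendro, datasets = mode_dendrogram_only(target, workdir, keywords)
    entries = analysis_pass(datasets, keywords)
    write_final_list(entries, workdir / "FINAL_list_of_files.dat")
    with open(workdir / "mtz_names.dat") as fh:
        paths = [line.strip() for line in fh if line.strip()]
    AnalysisState(paths=paths, entries=entries, workdir=str(workdir)).save()
    return dendro, entries


# ---------------------------------------------------------------------------
# synthesis


def _stats_row(tag, stats: MergeStats) -> str:
    def fmt(x, width=8, prec=3):
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return " " * (width - 3) + "---"
        return f"{x:{width}.{prec}f}"

    return (
        f"{str(tag):>8} {fmt(stats.r_meas)} {fmt(stats.r_pim)} "
        f"{fmt(stats.completeness, prec=2)} {fmt(stats.multiplicity, prec=2)} "
        f"{fmt(stats.res_cc, prec=2)} {fmt(stats.res_mnisd, prec=2)} "
        f"{fmt(stats.res_max, prec=2)}\n"
    )


_STATS_HEADER = (
    "# cluster   R_meas    R_pim   Compl.   Multipl.  ResCC1/2  ResMn(I/sd)  ResMax\n"
)


def _write_group_files(result: MergeResult, outdir: Path, tag: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    scaled = result.scaled
    with open(outdir / f"group_{tag}_scaled.dat", "w") as fh:
        fh.write("H K L I SIGI SERIAL IMAGE\n")
        for r in scaled.itertuples():
            fh.write(
                f"{int(r.key_h)} {int(r.key_k)} {int(r.key_l)} "
                f"{r.intensity:.6g} {r.sigma:.6g} {int(r.serial)} {int(r.image)}\n"
            )
    with open(outdir / f"group_{tag}_merged.dat", "w") as fh:
        fh.write("H K L I SIGI NOBS\n")
        for r in result.reflections.itertuples():
            fh.write(
                f"{int(r.key_h)} {int(r.key_k)} {int(r.key_l)} "
                f"{r.intensity:.6g} {r.sigma:.6g} {int(r.n_obs)}\n"
            )
    st = result.stats
    with open(outdir / f"group_{tag}.log", "w") as fh:
        fh.write(f"group {tag}: members {result.members}\n")
        for serial, (k, b) in result.scales.items():
            fh.write(f"  scale dataset {serial}: k={k:.6g} B={b:.6g}\n")
        fh.write(
            f"  R_merge={st.r_merge} R_meas={st.r_meas} R_pim={st.r_pim}\n"
            f"  completeness={st.completeness:.2f}% multiplicity={st.multiplicity:.2f}\n"
            f"  CC1/2={st.cc_half:.4f} Mn(I/sd)={st.mn_i_sd:.2f}\n"
            f"  res_cc={st.res_cc:.3f} res_mnisd={st.res_mnisd:.3f} res_max={st.res_max:.3f}\n"
        )
        if st.per_shell is not None:
            fh.write(st.per_shell.to_string(index=False) + "\n")


def mode_synthesis(
    workdir: str | Path,
    threshold_kind: str,
    threshold: float,
    keywords: KeywordSet | None = None,
) -> dict[int, MergeResult]:
    """Scale and merge every dendrogram node admitted by the threshold.

    ``threshold_kind`` is 'height' (merge height) or 'alcv' (Angstrom).
    Writes merged_files/ and a MERGING_STATISTICS.info table sorted by
    descending completeness.
    """
    keywords = keywords or KeywordSet()
    workdir = Path(workdir)
    state = AnalysisState.load(workdir)
    datasets = state.load_datasets()
    dendro = build_dendrogram(datasets)
    selected = cut_tree(dendro, threshold_kind, threshold)
    if not selected:
        log.warning("no dendrogram node admitted by %s <= %s", threshold_kind, threshold)
    merged_dir = workdir / "merged_files"
    merged_dir.mkdir(parents=True, exist_ok=True)
    by_serial = {ds.serial: ds for ds in datasets}
    results: dict[int, MergeResult] = {}
    for node in selected:
        group = [by_serial[s] for s in sorted(node.members)]
        result = merge_group(group, keywords=keywords, tag=str(node.node_id))
        results[node.node_id] = result
        _write_group_files(result, merged_dir, str(node.node_id))
    rows = sorted(
        results.items(), key=lambda kv: kv[1].stats.completeness, reverse=True
    )
    with open(workdir / STATS_FILE, "w") as fh:
        fh.write(_STATS_HEADER)
        for node_id, result in rows:
            fh.write(_stats_row(node_id, result.stats))
    return results


# ---------------------------------------------------------------------------
# combination syntax


@dataclass
class CombinationSpec:
    """Include cluster node_ids / dataset serials; exclude dataset serials."""

    include: list[int]
    exclude: list[int] = field(default_factory=list)

    def expand(self, dendro: Dendrogram) -> list[int]:
        serials: set[int] = set()
        n = dendro.n_leaves
        for ident in self.include:
            if n + 1 <= ident <= 2 * n - 1:
                serials |= dendro.node(ident).members
            elif ident in dendro.cells:
                serials.add(ident)
            else:
                raise ValueError(f"unknown cluster or dataset id {ident}")
        for ident in self.exclude:
            if ident not in dendro.cells:
                raise ValueError(f"unknown dataset serial {ident} in exclusion")
        serials -= set(self.exclude)
        if not serials:
            raise ValueError("combination expands to an empty dataset set")
        return sorted(serials)


def parse_combination(tokens: Sequence[str] | str) -> CombinationSpec:
    """Parse '[a,b,...]' include and optional '[[c,d,...]]' exclude tokens."""
    if isinstance(tokens, str):
        text = tokens
    else:
        text = " ".join(tokens)
    exclude: list[int] = []
    for m in re.finditer(r"\[\[([0-9,\s]+)\]\]", text):
        exclude.extend(int(x) for x in m.group(1).replace(",", " ").split())
    text_wo = re.sub(r"\[\[([0-9,\s]+)\]\]", " ", text)
    include: list[int] = []
    for m in re.finditer(r"\[([0-9,\s]+)\]", text_wo):
        include.extend(int(x) for x in m.group(1).replace(",", " ").split())
    if not include:
        raise ValueError(f"no include group found in combination spec {text!r}")
    return CombinationSpec(include=include, exclude=exclude)


def _next_run_number(combined_dir: Path) -> int:
    existing = [
        int(m.group(1))
        for p in combined_dir.glob("run_*")
        if (m := re.match(r"run_(\d+)$", p.name))
    ]
    return max(existing, default=0) + 1


def mode_combination(
    spec: CombinationSpec | str,
    workdir: str | Path,
    keywords: KeywordSet | None = None,
) -> MergeResult:
    """Merge an arbitrary include/exclude dataset selection.

    Outputs go to combined_files/run_<k>/ with sequential run numbering;
    the statistics row is appended to combined_files/MERGING_STATISTICS.info.
    """
    keywords = keywords or KeywordSet()
    workdir = Path(workdir)
    if isinstance(spec, str):
        spec = parse_combination(spec)
    state = AnalysisState.load(workdir)
    datasets = state.load_datasets()
    dendro = build_dendrogram(datasets)
    serials = spec.expand(dendro)
    by_serial = {ds.serial: ds for ds in datasets}
    group = [by_serial[s] for s in serials]
    combined_dir = workdir / "combined_files"
    combined_dir.mkdir(parents=True, exist_ok=True)
    run = _next_run_number(combined_dir)
    tag = f"run{run}"
    result = merge_group(group, keywords=keywords, tag=tag)
    _write_group_files(result, combined_dir / f"run_{run}", tag)
    stats_path = combined_dir / STATS_FILE
    new = not stats_path.exists()
    with open(stats_path, "a") as fh:
        if new:
            fh.write(_STATS_HEADER)
        fh.write(_stats_row(",".join(map(str, serials)), result.stats))
    return result


# ---------------------------------------------------------------------------
# pruning


@dataclass
class PruneCycle:
    cycle: int
    images_removed_total: int
    ranges: dict[int, tuple[int, int]]   # serial -> accepted (first, last)
    stats: MergeStats
    victim: int | None = None            # dataset pruned to produce this cycle


def _per_dataset_r_merge(result: MergeResult) -> dict[int, float]:
    """Each dataset's own R_merge contribution on the current scaling:
    sum |I_hi - <I_h>| over its observations / sum I_hi over its observations,
    restricted to multiply-observed reflections."""
    scaled = result.scaled
    from .scalemerge import _encode

    code = _encode(scaled[["key_h", "key_k", "key_l"]].to_numpy())
    uniq, keyinv = np.unique(code, return_inverse=True)
    counts = np.bincount(keyinv)
    I = scaled["intensity"].to_numpy()
    means = np.bincount(keyinv, weights=I) / counts
    dev = np.abs(I - means[keyinv])
    multi = counts[keyinv] >= 2
    serials = scaled["serial"].to_numpy()
    out = {}
    for serial in np.unique(serials):
        m = (serials == serial) & multi
        den = I[m].sum()
        out[int(serial)] = float(dev[m].sum() / den) if den > 0 else float("inf")
    return out


def mode_pruning(
    spec: CombinationSpec | str,
    workdir: str | Path,
    keywords: KeywordSet | None = None,
) -> tuple[PruneCycle, list[PruneCycle]]:
    """Iterative image-tail pruning to minimise R_pim at a completeness floor.

    Cycle 0 merges the unpruned selection.  Each subsequent cycle removes the
    trailing ``prune_fraction`` (at least one image) of the currently
    accepted range of the dataset with the highest per-dataset mean R_merge,
    then re-merges.  Cycling halts when completeness drops below the target,
    a dataset would be fully eliminated, or ``max_prune_cycles`` is reached.
    The returned best cycle has the lowest R_pim among cycle 0 and all
    cycles meeting the completeness target.
    """
    keywords = keywords or KeywordSet()
    workdir = Path(workdir)
    if isinstance(spec, str):
        spec = parse_combination(spec)
    state = AnalysisState.load(workdir)
    datasets = state.load_datasets()
    if len(datasets) < 2:
        raise ValueError("pruning needs at least 2 datasets")
    dendro = build_dendrogram(datasets)
    serials = spec.expand(dendro)
    if len(serials) < 2:
        raise ValueError("pruning needs at least 2 datasets in the selection")
    by_serial = {ds.serial: ds for ds in datasets}
    ranges = {s: (by_serial[s].first_image, by_serial[s].last_image) for s in serials}
    cycles: list[PruneCycle] = []
    removed_total = 0
    victim = None
    for cycle in range(keywords.max_prune_cycles + 1):
        group = [
            by_serial[s].truncated(first=ranges[s][0], last=ranges[s][1])
            for s in serials
        ]
        result = merge_group(group, keywords=keywords, tag=f"prune{cycle}")
        cycles.append(
            PruneCycle(
                cycle=cycle,
                images_removed_total=removed_total,
                ranges=dict(ranges),
                stats=result.stats,
                victim=victim,
            )
        )
        if cycle > 0 and result.stats.completeness < keywords.completeness_target:
            log.info("pruning halted: completeness below target at cycle %d", cycle)
            break
        if cycle == keywords.max_prune_cycles:
            break
        contrib = _per_dataset_r_merge(result)
        victim = max(contrib, key=contrib.get)
        first, last = ranges[victim]
        n_acc = last - first + 1
        n_remove = max(1, int(math.floor(keywords.prune_fraction * n_acc)))
        new_last = last - n_remove
        if new_last < first:
            log.info("pruning halted: dataset %d would be fully eliminated", victim)
            break
        ranges[victim] = (first, new_last)
        removed_total += n_remove
    eligible = [
        c
        for c in cycles
        if c.cycle == 0 or c.stats.completeness >= keywords.completeness_target
    ]
    best = min(eligible, key=lambda c: (c.stats.r_pim if c.stats.r_pim is not None else math.inf))
    prune_dir = workdir / "combined_files"
    prune_dir.mkdir(parents=True, exist_ok=True)
    with open(prune_dir / "PRUNING.log", "a") as fh:
        fh.write(
            f"# pruning of {','.join(map(str, serials))}: "
            f"best cycle {best.cycle} (R_pim {best.stats.r_pim})\n"
        )
        fh.write("# cycle removed victim  R_merge  R_meas   R_pim  Compl.\n")
        for c in cycles:
            st = c.stats
            fh.write(
                f"{c.cycle:6d} {c.images_removed_total:7d} "
                f"{c.victim if c.victim is not None else '-':>6} "
                f"{st.r_merge:.4f} {st.r_meas:.4f} {st.r_pim:.4f} {st.completeness:7.2f}\n"
            )
    return best, cycles


# ---------------------------------------------------------------------------
# graphics


def mode_graphics(
    workdir: str | Path,
    node_id: int,
    levels: int,
    annotations: "plots.AnnotationTable | None" = None,
) -> Path:
    """Render the annotated subtree around one cluster into graphics/."""
    workdir = Path(workdir)
    state = AnalysisState.load(workdir)
    datasets = state.load_datasets()
    dendro = build_dendrogram(datasets)
    outdir = workdir / "graphics"
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"tree_{node_id}_{levels}.png"
    plots.plot_subtree(dendro, node_id, levels, annotations=annotations, path=path)
    return path
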