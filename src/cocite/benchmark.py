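"""Evaluation harness: Fisher's-exact overlap baseline vs co-citation scoring.

Conventional gene-set enrichment compares two sets by their gene overlap
(one-sided hypergeometric / Fisher's exact test).  Co-citation scoring needs
no shared genes at all: two sets discussed in the same literature score high
even when disjoint.  This module reproduces that comparison on labeled
positive/negative set pairs via ROC curves.

Scores for ROC ranking default to (1 - p) for the permutation-based modes
(size-adjusted); raw CI is available via ``score_by="ci"``.  Fisher pairs
are scored by (1 - p) of the overlap test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from statsmodels.stats.multitest import multipletests

from .cocitation import gene_gene_analysis, gene_term_analysis
from .corpus import CitationIndex, GeneSet, HomologTable, TermSet

__all__ = [
    "BenchmarkPair",
    "RocCurve",
    "BenchmarkReport",
    "fisher_overlap_test",
    "bh_correct",
    "roc_auc",
    "run_benchmark",
    "read_benchmark_pairs",
    "write_benchmark_pairs",
]


@dataclass(frozen=True)
class BenchmarkPair:
    """One labeled pair: gene set A vs gene set B and/or a term set."""

    pair_id: str
    label: str  # "positive" | "negative"
    set_a: GeneSet
    set_b: Optional[GeneSet] = None
    terms: Optional[TermSet] = None

    def __post_init__(self):
        if self.label not in {"positive", "negative"}:
            raise ValueError(f"label must be positive|negative, got {self.label!r}")
        if self.set_b is None and self.terms is None:
            raise ValueError(f"pair {self.pair_id}: needs a target gene set or term set")


@dataclass(frozen=True)
class RocCurve:
    """An ROC curve from (0,0) to (1,1) with its trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def fisher_overlap_test(
    a: Union[GeneSet, Iterable[str]],
    b: Union[GeneSet, Iterable[str]],
    universe: Union[GeneSet, Iterable[str]],
) -> float:
    """One-sided (over-enrichment) Fisher's exact test on gene overlap.

    Hypergeometric tail probability of drawing at least ``|A ∩ B|`` of the
    ``|A|`` "marked" genes when ``|B|`` genes are sampled from ``universe``.
    """
    set_a = set(a.genes) if isinstance(a, GeneSet) else set(a)
    set_b = set(b.genes) if isinstance(b, GeneSet) else set(b)
    uni = set(universe.genes) if isinstance(universe, GeneSet) else set(universe)
    if len(uni) < 2:
        raise ValueError("universe must have at least 2 genes")
    if not set_a <= uni:
        raise ValueError(f"set A has {len(set_a - uni)} gene(s) outside the universe")
    if not set_b <= uni:
        raise ValueError(f"set B has {len(set_b - uni)} gene(s) outside the universe")
    k = len(set_a & set_b)
    return float(hypergeom.sf(k - 1, len(uni), len(set_a), len(set_b)))


def bh_correct(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def _as_bool_labels(labels: Sequence) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, str):
            out.append(lab.lower() in {"positive", "pos", "1", "true"})
        else:
            out.append(bool(lab))
    return np.asarray(out, dtype=bool)


def roc_auc(scores: Sequence[float], labels: Sequence) -> RocCurve:
    """ROC by threshold sweep; tied scores share a diagonal segment; AUC by
    trapezoid (equal to the tie-corrected Mann-Whitney rank statistic)."""
    y = _as_bool_labels(labels)
    s = np.asarray(list(scores), dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, thr = _roc_curve(y, s, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_trapezoid_auc(fpr, tpr)))


@dataclass
class BenchmarkReport:
    scores: pd.DataFrame  # pair_id, label, one score column per method
    curves: Dict[str, RocCurve]

    @property
    def aucs(self) -> Dict[str, float]:
        return {m: c.auc for m, c in self.curves.items()}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        summary = []
        n_pos = int((self.scores["label"] == "positive").sum())
        n_neg = int((self.scores["label"] == "negative").sum())
        for method, curve in self.curves.items():
            pd.DataFrame({"fpr": curve.fpr, "tpr": curve.tpr}).to_csv(
                outdir / f"roc_{method}.tsv", sep="\t", index=False
            )
            summary.append(
                {"method": method, "auc": curve.auc, "n_pos": n_pos, "n_neg": n_neg}
            )
        with open(outdir / "roc_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2)
            fh.write("\n")

    def plot(self, path) -> None:
        """ROC overlay of all methods (matplotlib, written to ``path``)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for method, curve in self.curves.items():
            ax.plot(curve.fpr, curve.tpr, label=f"{method} (AUC={curve.auc:.2f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def run_benchmark(
    pairs: Sequence[BenchmarkPair],
    index: CitationIndex,
    store=None,
    homologs: Optional[HomologTable] = None,
    n_perm: int = 200,
    seed: int = 0,
    universe: Optional[Set[str]] = None,
    score_by: str = "p",
) -> BenchmarkReport:
    """Score every pair with every applicable method and build ROC curves.

    Methods: ``gene_gene`` (needs set_b), ``gene_term`` (needs terms and a
    store), ``fisher`` (needs set_b).  A pair missing the input of an active
    method is an error, never a silent skip.
    """
    if not pairs:
        raise ValueError("no benchmark pairs")
    if score_by not in {"p", "ci"}:
        raise ValueError(f"score_by must be 'p' or 'ci', got {score_by!r}")
    do_gg = pairs[0].set_b is not None
    do_gt = pairs[0].terms is not None and store is not None
    if not do_gg and not do_gt:
        raise ValueError("pairs carry neither target gene sets nor term sets")

    if universe is None:
        tax = pairs[0].set_a.tax_id
        universe = set(index.genes(tax))

    rng = np.random.default_rng(seed)
    term_cache: Dict[Tuple[str, ...], List[Set[int]]] = {}
    rows = []
    for pair in pairs:
        row: Dict[str, object] = {"pair_id": pair.pair_id, "label": pair.label}
        if do_gg:
            if pair.set_b is None:
                raise ValueError(f"pair {pair.pair_id} lacks a target gene set")
            gg = gene_gene_analysis(
                pair.set_a, pair.set_b, index, homologs=homologs,
                n_perm=n_perm, seed=int(rng.integers(2**31)),
            ).result
            row["gene_gene"] = gg.ci if score_by == "ci" else 1.0 - gg.p_value
            row["gene_gene_p"] = gg.p_value
            row["fisher_p"] = fisher_overlap_test(pair.set_a, pair.set_b, universe)
            row["fisher"] = 1.0 - row["fisher_p"]
        if do_gt:
            if pair.terms is None:
                raise ValueError(f"pair {pair.pair_id} lacks a term set")
            gt = gene_term_analysis(
                pair.set_a, pair.terms, index, store, homologs=homologs,
                n_perm=n_perm, seed=int(rng.integers(2**31)),
            )
            row["gene_term"] = gt.ci if score_by == "ci" else 1.0 - gt.p_value
            row["gene_term_p"] = gt.p_value
        rows.append(row)

    scores = pd.DataFrame(rows)
    methods = [m for m in ("gene_gene", "gene_term", "fisher") if m in scores.columns]
    curves = {
        m: roc_auc(scores[m].to_numpy(), scores["label"].tolist()) for m in methods
    }
    return BenchmarkReport(scores=scores, curves=curves)


# ------------------------------------------------------------- pair files


def write_benchmark_pairs(pairs: Sequence[BenchmarkPair], outdir) -> Path:
    """Write a pair table (TSV) plus one set/term file per column entry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = outdir / "pairs.tsv"
    with open(table, "w", encoding="utf-8") as fh:
        fh.write("pair_id\tlabel\tset_a\tset_b_or_terms\tmode\n")
        for pair in pairs:
            a_path = outdir / f"{pair.pair_id}_a.txt"
            with open(a_path, "w", encoding="utf-8") as gfh:
                gfh.write(f"taxid:{pair.set_a.tax_id}\n")
                gfh.writelines(g + "\n" for g in pair.set_a.genes)
            if pair.set_b is not None:
                b_path = outdir / f"{pair.pair_id}_b.txt"
                with open(b_path, "w", encoding="utf-8") as gfh:
                    gfh.write(f"taxid:{pair.set_b.tax_id}\n")
                    gfh.writelines(g + "\n" for g in pair.set_b.genes)
                fh.write(f"{pair.pair_id}\t{pair.label}\t{a_path.name}\t{b_path.name}\tgene-gene\n")
            if pair.terms is not None:
                t_path = outdir / f"{pair.pair_id}_t.txt"
                with open(t_path, "w", encoding="utf-8") as tfh:
                    tfh.writelines(t + "\n" for t in pair.terms.terms)
                fh.write(f"{pair.pair_id}\t{pair.label}\t{a_path.name}\t{t_path.name}\tgene-term\n")
    return table


def read_benchmark_pairs(table_path, tax_id: Optional[int] = None) -> List[BenchmarkPair]:
    """Read a pair table written by :func:`write_benchmark_pairs`.

    Rows sharing a pair_id (one gene-gene, one gene-term) are merged into a
    single :class:`BenchmarkPair`.
    """
    table_path = Path(table_path)
    base = table_path.parent
    partial: Dict[str, Dict[str, object]] = {}
    with open(table_path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("pair_id"):
            raise ValueError(f"{table_path}: missing pair-table header")
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            pair_id, label, a_name, target_name, mode = line.split("\t")
            entry = partial.setdefault(pair_id, {"label": label})
            if "set_a" not in entry:
                entry["set_a"] = GeneSet.from_file(base / a_name, tax_id=tax_id)
            if mode == "gene-gene":
                entry["set_b"] = GeneSet.from_file(base / target_name, tax_id=tax_id)
            elif mode == "gene-term":
                entry["terms"] = TermSet.from_file(base / target_name)
            else:
                raise ValueError(f"{table_path}: unknown mode {mode!r}")
    return [
        BenchmarkPair(
            pair_id=pid,
            label=str(entry["label"]),
            set_a=entry["set_a"],  # type: ignore[arg-type]
            set_b=entry.get("set_b"),  # type: ignore[arg-type]
            terms=entry.get("terms"),  # type: ignore[arg-type]
        )
        for pid, entry in partial.items()
    ]
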