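"""Classifier and assay evaluation.

Implements the leave-out cross-validation design used to benchmark
mini-barcode reference libraries: dereplicate at 100% identity, repeatedly
hold out a fraction of the sequences, classify them against the remainder,
and score each held-out sequence at each rank and confidence threshold as
correct, false positive (classified at the rank but to the wrong taxon) or
false negative (not classified at the rank).  The three categories
partition the held-out set, so correct% + FP% + FN% = 100 in every cell.

Also: a confidence-threshold sweep that re-thresholds the same bootstrap
trials (no re-sampling across thresholds), leave-self-out top-hit panel
resolution, and mock-community detection metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import Call, NaiveBayesKmerClassifier, TopHitClassifier
from .readpipe import SampleProfile
from .seqcore import RANKS, RefRecord, TaxonLineage

__all__ = [
    "EvalDesign",
    "ResolutionReport",
    "leave_out_eval",
    "threshold_sweep",
    "panel_resolution",
    "detection_metrics",
    "plot_sweep",
]

DEFAULT_THRESHOLDS = tuple(round(0.5 + 0.05 * i, 2) for i in range(11))


@dataclass(frozen=True)
class EvalDesign:
    """Leave-out evaluation design: hold out fraction ``p`` of the
    dereplicated library, ``replicates`` times, scoring the listed ranks."""

    p: float = 0.05
    replicates: int = 5
    ranks: tuple = ("genus", "species")
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _dereplicate_exact(records: Sequence[RefRecord]) -> list:
    seen: set = set()
    out = []
    for rec in sorted(records, key=lambda r: r.id):
        if rec.sequence in seen:
            continue
        seen.add(rec.sequence)
        out.append(rec)
    return out


def _score_cell(calls: Sequence[Call], truths: Sequence[TaxonLineage],
                rank: str, threshold: float):
    """(correct%, fp%, fn%) for held-out calls at one rank/threshold."""
    n = correct = fp = fn = 0
    for call, truth in zip(calls, truths):
        true_taxon = truth.get(rank)
        if true_taxon is None:
            continue
        n += 1
        taxon, conf = call.assignments[rank]
        if taxon is not None and conf >= threshold:
            if taxon == true_taxon:
                correct += 1
            else:
                fp += 1
        else:
            fn += 1
    if n == 0:
        return float("nan"), float("nan"), float("nan"), 0
    return 100 * correct / n, 100 * fp / n, 100 * fn / n, n


def threshold_sweep(library: Sequence[RefRecord],
                    design: EvalDesign = EvalDesign(),
                    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                    k: int = 8, n_bootstrap: int = 100,
                    word_fraction: float = 0.125) -> pd.DataFrame:
    """Leave-out evaluation across confidence thresholds.

    Bootstrap trials are computed once per held-out query and re-thresholded,
    so FP% is non-increasing and FN% non-decreasing in the threshold by
    construction.  Held-out sequences whose species is absent from the
    training split remain in the denominator (they can only score FP or FN
    at species level), mirroring classification against incomplete
    reference databases.

    Returns a tidy DataFrame with columns replicate, rank, threshold, n,
    correct, fp, fn (percentages).
    """
    derep = _dereplicate_exact(library)
    n = len(derep)
    n_hold = math.ceil(design.p * n)
    if n_hold >= n:
        raise ValueError("library too small for the requested holdout")
    rows = []
    for rep in range(design.replicates):
        rng = np.random.default_rng(design.seed + rep)
        hold_idx = set(rng.choice(n, size=n_hold, replace=False).tolist())
        train = [derep[i] for i in range(n) if i not in hold_idx]
        held = [derep[i] for i in sorted(hold_idx)]
        clf = NaiveBayesKmerClassifier(
            k=k, n_bootstrap=n_bootstrap, word_fraction=word_fraction,
            random_state=design.seed + rep)
        clf.fit([r.sequence for r in train],
                [r.lineage.species for r in train],
                lineages={r.lineage.species: r.lineage for r in train})
        calls = clf.predict_calls([r.sequence for r in held],
                                  ids=[r.id for r in held])
        truths = [r.lineage for r in held]
        for rank in design.ranks:
            for c in thresholds:
                correct, fp, fn, n_cell = _score_cell(calls, truths, rank, c)
                rows.append({"replicate": rep + 1, "rank": rank,
                             "threshold": c, "n": n_cell,
                             "correct": correct, "fp": fp, "fn": fn})
    return pd.DataFrame(rows)


def leave_out_eval(library: Sequence[RefRecord],
                   design: EvalDesign = EvalDesign(),
                   threshold: float = 0.8, **kwargs) -> pd.DataFrame:
    """Leave-out evaluation at a single confidence threshold."""
    return threshold_sweep(library, design, thresholds=(threshold,), **kwargs)


@dataclass
class ResolutionReport:
    """Panel resolution outcome counts; the three categories partition the
    panel and the percentages sum to 100."""

    n_species: int
    species_resolved: int
    congener_shared: int
    cross_genus_shared: int
    per_species: pd.DataFrame = field(repr=False, default=None)

    @property
    def pct_resolved(self) -> float:
        return 100 * self.species_resolved / self.n_species

    @property
    def pct_congener(self) -> float:
        return 100 * self.congener_shared / self.n_species

    @property
    def pct_cross_genus(self) -> float:
        return 100 * self.cross_genus_shared / self.n_species


def panel_resolution(panel: Sequence[RefRecord],
                     tie_epsilon: float = 0.0) -> ResolutionReport:
    """Leave-self-out top-hit resolution over a one-barcode-per-species
    panel.

    A species is species-resolved when its barcode is not shared (identity
    1.0) with any other species; species sharing a barcode are scored
    congener-shared when every tie-set member is congeneric, else
    cross-genus-shared.  Input order does not affect the result.
    """
    panel = sorted(panel, key=lambda r: r.lineage.species or r.id)
    species = [r.lineage.species for r in panel]
    if len(set(species)) != len(species) or None in species:
        raise ValueError("panel must hold exactly one record per species")
    clf = TopHitClassifier(tie_epsilon=tie_epsilon)
    clf.fit([r.sequence for r in panel], species,
            lineages={r.lineage.species: r.lineage for r in panel})
    rows = []
    n_res = n_cong = n_cross = 0
    for i, rec in enumerate(panel):
        hit = clf.predict_tophit(rec.sequence, query_id=rec.id, exclude={i})
        if hit.best_identity < 1.0:
            category = "species_resolved"
            n_res += 1
        else:
            genera = {clf.lineage_map_[s].genus for s in hit.tie_species}
            genera.add(rec.lineage.genus)
            if len(genera) == 1:
                category = "congener_shared"
                n_cong += 1
            else:
                category = "cross_genus_shared"
                n_cross += 1
        rows.append({"species": rec.lineage.species, "category": category,
                     "best_identity": hit.best_identity,
                     "tie_species": ";".join(hit.tie_species)})
    return ResolutionReport(n_species=len(panel), species_resolved=n_res,
                            congener_shared=n_cong, cross_genus_shared=n_cross,
                            per_species=pd.DataFrame(rows))


def detection_metrics(profile: SampleProfile,
                      truth_species: Iterable[str]) -> dict:
    """Sensitivity and per-sample species-list specificity (percent).

    Sensitivity = detected true species / true species; specificity = 100
    when no detected species falls outside the truth set, else the fraction
    of detections that are true.
    """
    truth = set(truth_species)
    if not truth:
        raise ValueError("empty truth set")
    detected = set(profile.detected)
    sensitivity = 100 * len(detected & truth) / len(truth)
    if not detected:
        specificity = 100.0
    else:
        specificity = 100 * len(detected & truth) / len(detected)
    return {"sensitivity": sensitivity, "specificity": specificity}


def plot_sweep(report: pd.DataFrame, path) -> None:
    """Two-panel threshold-sweep figure (genus and species), mean over
    replicates."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranks = [r for r in ("genus", "species") if r in set(report["rank"])]
    fig, axes = plt.subplots(1, max(len(ranks), 1), figsize=(5 * len(ranks), 4),
                             squeeze=False)
    for ax, rank in zip(axes[0], ranks):
        sub = (report[report["rank"] == rank]
               .groupby("threshold")[["correct", "fp", "fn"]].mean())
        for col, label in [("correct", "correct"), ("fp", "false positive"),
                           ("fn", "false negative")]:
            ax.plot(sub.index, sub[col], marker="o", label=label)
        ax.set_xlabel("confidence threshold")
        ax.set_ylabel("% of held-out sequences")
        ax.set_title(rank)
        ax.set_ylim(-2, 102)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
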