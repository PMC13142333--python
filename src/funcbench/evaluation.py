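"""Protein-centric prospective evaluation: NK/LK/PK partitioning, threshold
curves, Fmax/Smin/coverage, and bootstrap confidence intervals.

Evaluation is per aspect and per knowledge setting:

* **NK** (no knowledge): the protein had no experimental non-root annotation
  in *any* aspect at t0 and gained terms in this aspect.
* **LK** (limited knowledge): annotated in at least one other aspect at t0,
  unannotated in this one, and gained terms here.
* **PK** (partial knowledge): already annotated in this aspect at t0 and
  gained further terms; only the newly added terms are ground truth, and the
  prior terms are removed from predictions before thresholding.

For each threshold tau in an ascending grid, precision/recall (optionally
information-accretion weighted, micro- or macro-averaged), coverage
m(tau)/n, and the semantic-distance components ru (remaining uncertainty)
and mi (misinformation) are computed; Fmax and Smin are read off the curves.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import TextIO

import numpy as np
import pandas as pd

from .accretion import IATable
from .annotations import AnnotationSet, GrowthSet
from .ontology import ASPECTS, OntologyGraph, UnknownTermError

logger = logging.getLogger(__name__)

SETTINGS = ("NK", "LK", "PK")

#: Default threshold grid: 0.01, 0.02, ..., 1.00.
DEFAULT_GRID = tuple(np.round(np.arange(1, 101) / 100, 2))

_CAFA_HEADER_KEYS = ("AUTHOR", "MODEL", "KEYWORDS", "ACCURACY", "END")


class PredictionSet:
    """Per-protein GO-term confidence scores in [0, 1]."""

    def __init__(
        self,
        scores: Mapping[str, Mapping[str, float]] | None = None,
        model_tag: str = "",
    ) -> None:
        self.model_tag = model_tag
        self.header: dict[str, str] = {}
        self._scores: dict[str, dict[str, float]] = {}
        if scores:
            for protein, terms in scores.items():
                for term, s in terms.items():
                    self.set_score(protein, term, s)

    def set_score(self, protein: str, term: str, score: float) -> None:
        score = float(score)
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"score {score} for ({protein}, {term}) outside [0, 1]")
        self._scores.setdefault(protein, {})[term] = score

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self._scores)

    def scores(self, protein: str) -> dict[str, float]:
        return dict(self._scores.get(protein, {}))

    def items(self) -> Iterable[tuple[str, dict[str, float]]]:
        for protein in sorted(self._scores):
            yield protein, dict(self._scores[protein])

    def __len__(self) -> int:
        return len(self._scores)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PredictionSet):
            return NotImplemented
        return self._scores == other._scores

    # ---------------------------------------------------------------- io
    @classmethod
    def from_file(cls, source: str | TextIO, model_tag: str = "") -> "PredictionSet":
        """Read a 3-column (protein, term, score) delimited file.

        CAFA-style ``AUTHOR``/``MODEL``/``KEYWORDS``/``END`` header lines are
        tolerated and recorded on :attr:`header`.
        """
        handle = open(source) if isinstance(source, str) else source
        out = cls(model_tag=model_tag)
        try:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if fields[0].upper() in _CAFA_HEADER_KEYS:
                    out.header[fields[0].upper()] = " ".join(fields[1:])
                    continue
                if len(fields) < 3:
                    raise ValueError(f"bad prediction row: {line!r}")
                out.set_score(fields[0], fields[1], float(fields[2]))
        finally:
            if isinstance(source, str):
                handle.close()
        if not out.model_tag:
            out.model_tag = out.header.get("MODEL", "")
        return out

    def to_file(self, target: str | TextIO) -> None:
        handle = open(target, "w") if isinstance(target, str) else target
        try:
            for protein, terms in self.items():
                for term in sorted(terms):
                    handle.write(f"{protein}\t{term}\t{terms[term]:.6f}\n")
        finally:
            if isinstance(target, str):
                handle.close()


@dataclass(frozen=True)
class PartitionEntry:
    """One evaluable protein-aspect pair."""

    protein: str
    aspect: str
    setting: str  # NK | LK | PK
    prior: frozenset[str]  # T_t0 (closure, may include the root)
    truth: frozenset[str]  # T_te \ T_t0, non-root, non-empty


class EvaluationPartition:
    """Per protein-aspect knowledge-setting labels with priors and ground truth."""

    def __init__(self, entries: Iterable[PartitionEntry], graph_version: str = "") -> None:
        self.graph_version = graph_version
        self._entries: dict[tuple[str, str], PartitionEntry] = {}
        for e in entries:
            if e.setting not in SETTINGS:
                raise ValueError(f"bad setting {e.setting!r}")
            if not e.truth:
                raise ValueError(f"entry ({e.protein}, {e.aspect}) has empty ground truth")
            self._entries[(e.protein, e.aspect)] = e

    def entry(self, protein: str, aspect: str) -> PartitionEntry | None:
        return self._entries.get((protein, aspect))

    def entries(
        self,
        setting: str | Iterable[str] | None = None,
        aspect: str | None = None,
    ) -> list[PartitionEntry]:
        if setting is None:
            settings = set(SETTINGS)
        elif isinstance(setting, str):
            settings = {setting}
        else:
            settings = set(setting)
        return sorted(
            (
                e
                for e in self._entries.values()
                if e.setting in settings and (aspect is None or e.aspect == aspect)
            ),
            key=lambda e: (e.protein, e.aspect),
        )

    def n(self, setting: str | Iterable[str] | None = None, aspect: str | None = None) -> int:
        return len(self.entries(setting, aspect))

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(sorted(self._entries.values(), key=lambda e: (e.protein, e.aspect)))


def partition_settings(t0: AnnotationSet, growth: GrowthSet, graph: OntologyGraph) -> EvaluationPartition:
    """Label every protein-aspect pair that gained terms as NK, LK or PK.

    A protein counts as "annotated in an aspect at t0" when it carries at
    least one non-root term there; root-only sets are information-free.
    """
    if t0.graph_version != growth.graph_version:
        raise ValueError("t0 snapshot and growth built on different graph versions")
    entries: list[PartitionEntry] = []
    for (protein, aspect), (prior, new) in growth.entries.items():
        annotated = t0.annotated_aspects(protein, graph)
        if aspect in annotated:
            setting = "PK"
        elif annotated:
            setting = "LK"
        else:
            setting = "NK"
        entries.append(PartitionEntry(protein, aspect, setting, frozenset(prior), frozenset(new)))
    return EvaluationPartition(entries, graph_version=growth.graph_version)


def prepare_predictions(
    preds: PredictionSet,
    graph: OntologyGraph,
    partition: EvaluationPartition | None = None,
    propagate: bool = True,
) -> PredictionSet:
    """Resolve prediction terms to the frozen graph and make them evaluable.

    Unknown terms are dropped with a counted warning.  With ``propagate``
    (the default) every ancestor receives the maximum of its own score and
    its descendants' scores, so thresholded prediction sets are
    ancestor-closed.  For PK entries the prior terms T_t0 are removed from
    that protein's predictions before thresholding; NK/LK predictions are
    untouched.
    """
    out = PredictionSet(model_tag=preds.model_tag)
    out.header = dict(preds.header)
    n_unknown = 0
    order = graph.topological_order() if propagate else None
    for protein, terms in preds.items():
        resolved: dict[str, float] = {}
        for term, score in terms.items():
            try:
                canon = graph.resolve(term)
            except UnknownTermError:
                n_unknown += 1
                continue
            resolved[canon] = max(score, resolved.get(canon, 0.0))
        if propagate:
            # children precede parents in `order`; push the max upward
            for term in order:
                if term in resolved:
                    s = resolved[term]
                    for parent in graph.parents(term):
                        if resolved.get(parent, -1.0) < s:
                            resolved[parent] = s
        if partition is not None:
            banned: set[str] = set()
            for aspect in ASPECTS:
                e = partition.entry(protein, aspect)
                if e is not None and e.setting == "PK":
                    banned |= e.prior
            for term in banned:
                resolved.pop(term, None)
        for term, score in resolved.items():
            out.set_score(protein, term, score)
    if n_unknown:
        warnings.warn(f"dropped {n_unknown} prediction(s) on unknown terms", stacklevel=2)
    return out


@dataclass
class MetricCurve:
    """Per-threshold metric values from which Fmax and Smin are read.

    ``pr`` is NaN wherever no protein has a prediction at that threshold
    (m(tau) = 0).  ``ru``/``mi`` are present only when an IA table was given.
    """

    thresholds: np.ndarray
    pr: np.ndarray
    rc: np.ndarray
    cov: np.ndarray
    m: np.ndarray
    n: int
    ru: np.ndarray | None = None
    mi: np.ndarray | None = None
    weighting: str = "unweighted"  # unweighted | ia
    averaging: str = "micro"  # micro | macro
    setting: str = ""
    aspect: str = ""


@dataclass(frozen=True)
class MetricSummary:
    """A single-number summary (Fmax or Smin) at its optimal threshold."""

    metric: str
    value: float
    tau: float
    coverage: float
    n: int
    weighting: str
    averaging: str
    setting: str = ""
    aspect: str = ""


@dataclass(frozen=True)
class BootstrapSummary:
    """Point estimate with a percentile bootstrap confidence interval."""

    point: float
    replicates: int
    mean: float
    level: float
    low: float
    high: float
    seed: int
    n_missing: int = 0


def _entry_arrays(
    entry: PartitionEntry,
    scores: Mapping[str, float],
    graph: OntologyGraph,
    ia: IATable | None,
):
    """Score / truth / weight arrays over the entry's candidate terms.

    Candidates are the union of the ground truth and the protein's non-root
    predictions within the entry's aspect.  Unpredicted truth terms carry
    score 0 and are never selected by a grid starting above 0.
    """
    aspect_terms = {
        t for t in scores if graph.aspect(t) == entry.aspect and not graph.is_root(t)
    }
    candidates = sorted(entry.truth | aspect_terms)
    s = np.array([scores.get(t, 0.0) for t in candidates])
    is_true = np.array([t in entry.truth for t in candidates], dtype=bool)
    w_ia = (
        np.array([ia.ia(t) for t in candidates]) if ia is not None else None
    )
    return s, is_true, w_ia


def metric_curves(
    preds: PredictionSet,
    partition: EvaluationPartition,
    setting: str | Iterable[str],
    aspect: str,
    graph: OntologyGraph,
    ia: IATable | None = None,
    weighting: str = "unweighted",
    averaging: str = "micro",
    grid: Sequence[float] = DEFAULT_GRID,
    entries: Sequence[PartitionEntry] | None = None,
    rumi_over_covered: bool = False,
) -> MetricCurve:
    """Precision/recall/coverage and ru/mi over an ascending threshold grid.

    ``weighting="ia"`` weighs every term by its information accretion (the
    table is then mandatory); ru/mi are always IA-weighted and are computed
    whenever a table is supplied.  ``averaging="micro"`` pools weights across
    proteins; ``"macro"`` averages per-protein precision over the m(tau)
    proteins with at least one prediction and per-protein recall over all n
    evaluable proteins.  ru/mi average over all n by default
    (``rumi_over_covered`` switches the denominator to m(tau)).

    ``entries`` overrides the evaluated protein list and may contain repeats
    (bootstrap resamples).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a non-empty ascending sequence")
    if np.any(grid <= 0) or np.any(grid > 1):
        raise ValueError("grid thresholds must lie in (0, 1]")
    if weighting not in ("unweighted", "ia"):
        raise ValueError(f"bad weighting {weighting!r}")
    if averaging not in ("micro", "macro"):
        raise ValueError(f"bad averaging {averaging!r}")
    if weighting == "ia" and ia is None:
        raise ValueError("IA table required for ia-weighted metrics")

    if entries is None:
        entries = partition.entries(setting, aspect)
    n = len(entries)
    if n == 0:
        raise ValueError(f"no evaluable proteins for setting={setting!r}, aspect={aspect!r}")

    G = len(grid)
    m = np.zeros(G, dtype=int)
    m_pr = np.zeros(G, dtype=int)  # proteins with positive predicted weight
    n_rc = 0  # proteins with positive truth weight
    sum_wtp = np.zeros(G)
    sum_wp = np.zeros(G)
    sum_wt = np.zeros(G)
    macro_pr = np.zeros(G)
    macro_rc = np.zeros(G)
    ru = np.zeros(G) if ia is not None else None
    mi = np.zeros(G) if ia is not None else None

    for entry in entries:
        scores = preds.scores(entry.protein)
        s, is_true, w_ia = _entry_arrays(entry, scores, graph, ia)
        pred_mask = s[:, None] >= grid[None, :]  # terms x thresholds
        any_pred = pred_mask.any(axis=0)
        m += any_pred

        w = w_ia if weighting == "ia" else np.ones(len(s))
        # accumulate W(P & T), W(P \ T), W(T \ P) directly so that the
        # perfect- and empty-predictor limits come out exactly 0/1
        wtp = (w[:, None] * pred_mask)[is_true].sum(axis=0)
        wfp = (w[:, None] * pred_mask)[~is_true].sum(axis=0)
        wfn = (w[:, None] * ~pred_mask)[is_true].sum(axis=0)
        wp = wtp + wfp
        wt = wtp + wfn
        sum_wtp += wtp
        sum_wp += wp
        sum_wt += wt
        # macro means run over proteins whose denominator weight is positive;
        # for unweighted metrics this is exactly "m(tau) covered proteins"
        # for precision and "all n" for recall (truth is never empty)
        m_pr += wp > 0
        has_truth_weight = bool(wt[0] > 0) if G else False
        n_rc += has_truth_weight
        with np.errstate(invalid="ignore", divide="ignore"):
            macro_pr += np.where(wp > 0, wtp / np.where(wp > 0, wp, 1.0), 0.0)
            macro_rc += np.where(wt > 0, wtp / np.where(wt > 0, wt, 1.0), 0.0)
        if ia is not None:
            ru += (w_ia[:, None] * ~pred_mask)[is_true].sum(axis=0)  # W(T \ P)
            mi += (w_ia[:, None] * pred_mask)[~is_true].sum(axis=0)  # W(P \ T)

    cov = m / n
    if averaging == "micro":
        with np.errstate(invalid="ignore", divide="ignore"):
            pr = np.where(m > 0, sum_wtp / np.where(sum_wp > 0, sum_wp, 1.0), np.nan)
            rc = np.where(sum_wt > 0, sum_wtp / np.where(sum_wt > 0, sum_wt, 1.0), 0.0)
    else:
        pr = np.where(m_pr > 0, macro_pr / np.where(m_pr > 0, m_pr, 1), np.nan)
        rc = macro_rc / n_rc if n_rc else np.zeros(G)
    if ia is not None:
        denom = np.where(m > 0, m, 1) if rumi_over_covered else n
        ru = ru / denom
        mi = mi / denom

    return MetricCurve(
        thresholds=grid,
        pr=pr,
        rc=rc,
        cov=cov,
        m=m,
        n=n,
        ru=ru,
        mi=mi,
        weighting=weighting,
        averaging=averaging,
        setting=setting if isinstance(setting, str) else "+".join(sorted(setting)),
        aspect=aspect,
    )


def fmax(curve: MetricCurve) -> MetricSummary:
    """Max over thresholds of the harmonic mean of precision and recall.

    Thresholds where precision is undefined (no predictions) are skipped;
    ties break toward the largest threshold.  A predictor with no defined
    point anywhere scores 0 at an undefined threshold.
    """
    if len(curve.thresholds) == 0:
        raise ValueError("empty curve")
    defined = ~np.isnan(curve.pr)
    if not defined.any():
        return MetricSummary(
            "fmax", 0.0, float("nan"), 0.0, curve.n,
            curve.weighting, curve.averaging, curve.setting, curve.aspect,
        )
    pr, rc = curve.pr[defined], curve.rc[defined]
    taus = curve.thresholds[defined]
    covs = curve.cov[defined]
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(pr + rc > 0, 2 * pr * rc / (pr + rc), 0.0)
    best = len(f1) - 1 - int(np.argmax(f1[::-1]))  # ties -> largest tau
    return MetricSummary(
        "fmax", float(f1[best]), float(taus[best]), float(covs[best]), curve.n,
        curve.weighting, curve.averaging, curve.setting, curve.aspect,
    )


def smin(curve: MetricCurve) -> MetricSummary:
    """Minimum semantic distance sqrt(ru^2 + mi^2) over thresholds.

    Defined at every threshold (an empty prediction set leaves all
    uncertainty remaining and no misinformation); ties break toward the
    largest threshold.
    """
    if curve.ru is None or curve.mi is None:
        raise ValueError("curve has no ru/mi components (no IA table supplied)")
    if len(curve.thresholds) == 0:
        raise ValueError("empty curve")
    s = np.sqrt(curve.ru**2 + curve.mi**2)
    best = len(s) - 1 - int(np.argmin(s[::-1]))
    return MetricSummary(
        "smin", float(s[best]), float(curve.thresholds[best]), float(curve.cov[best]),
        curve.n, "ia", curve.averaging, curve.setting, curve.aspect,
    )


def aggregate_score(per_aspect_fmax: Mapping[str, float]) -> float:
    """Arithmetic mean of the three per-aspect Fmax values.

    This is the single-number challenge ranking score when the inputs are the
    IA-weighted Fmax values computed on the union of NK and LK entries.
    """
    missing = set(ASPECTS) - set(per_aspect_fmax)
    if missing:
        raise ValueError(f"missing aspect(s): {sorted(missing)}")
    return float(np.mean([per_aspect_fmax[a] for a in ASPECTS]))


def bootstrap_metric(
    metric: Callable[[Sequence[PartitionEntry]], float],
    entries: Sequence[PartitionEntry],
    B: int = 5000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapSummary:
    """Percentile bootstrap over proteins sampled with replacement.

    ``metric`` is re-evaluated on each same-size resample of the evaluable
    entry list.  Replicates where the metric is undefined (NaN) are recorded
    as missing; more than 50% missing is an error.  Identical seeds give
    identical output.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not entries:
        raise ValueError("no entries to resample")
    rng = np.random.default_rng(seed)
    point = float(metric(entries))
    reps = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, len(entries), size=len(entries))
        try:
            reps[b] = metric([entries[i] for i in idx])
        except (ValueError, ZeroDivisionError):
            reps[b] = np.nan
    missing = int(np.isnan(reps).sum())
    if missing > B / 2:
        raise ValueError(f"metric undefined on {missing}/{B} bootstrap replicates")
    valid = reps[~np.isnan(reps)]
    alpha = (1.0 - level) / 2.0
    low, high = np.percentile(valid, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapSummary(
        point=point,
        replicates=B,
        mean=float(valid.mean()),
        level=level,
        low=float(low),
        high=float(high),
        seed=seed,
        n_missing=missing,
    )


def summarize_dataset(
    partition: EvaluationPartition,
    ia: IATable | None = None,
) -> pd.DataFrame:
    """Tidy per-(setting, aspect) counts of evaluable proteins and new terms.

    Term counts are propagated, root-excluded ground-truth sizes.  Setting
    rows ("total" aspect) and a grand-total row are appended; protein totals
    de-duplicate proteins that appear in several settings or aspects.
    """
    rows = []
    for setting in SETTINGS:
        for aspect in ASPECTS:
            es = partition.entries(setting, aspect)
            row = {
                "setting": setting,
                "aspect": aspect,
                "proteins": len({e.protein for e in es}),
                "terms": sum(len(e.truth) for e in es),
            }
            if ia is not None:
                row["information"] = float(sum(ia.weight(e.truth) for e in es))
            rows.append(row)
    df = pd.DataFrame(rows)
    totals = []
    for setting in SETTINGS:
        es = partition.entries(setting)
        t = {
            "setting": setting,
            "aspect": "total",
            "proteins": len({e.protein for e in es}),
            "terms": sum(len(e.truth) for e in es),
        }
        if ia is not None:
            t["information"] = float(sum(ia.weight(e.truth) for e in es))
        totals.append(t)
    grand = {
        "setting": "total",
        "aspect": "total",
        "proteins": len({e.protein for e in partition}),
        "terms": sum(len(e.truth) for e in partition),
    }
    if ia is not None:
        grand["information"] = float(sum(ia.weight(e.truth) for e in partition))
    return pd.concat([df, pd.DataFrame(totals + [grand])], ignore_index=True)


def evaluate_model(
    preds: PredictionSet,
    partition: EvaluationPartition,
    graph: OntologyGraph,
    ia: IATable | None = None,
    settings: Sequence[str] = SETTINGS,
    aspects: Sequence[str] = ASPECTS,
    weightings: Sequence[str] = ("unweighted", "ia"),
    averagings: Sequence[str] = ("micro", "macro"),
    grid: Sequence[float] = DEFAULT_GRID,
    bootstrap: int = 0,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Fmax (and Smin where IA is available) for every requested combination.

    Returns one tidy row per (setting, aspect, metric, weighting, averaging)
    with the optimal threshold, coverage there, n, and optional bootstrap CI.
    Predictions must already be prepared (see :func:`prepare_predictions`).
    """
    rows = []
    for setting in settings:
        for aspect in aspects:
            entries = partition.entries(setting, aspect)
            if not entries:
                logger.info("no evaluable entries for %s/%s; skipped", setting, aspect)
                continue
            for averaging in averagings:
                usable_weightings = [w for w in weightings if w != "ia" or ia is not None]
                for w in usable_weightings:
                    def _fmax_on(es, _w=w, _avg=averaging):
                        c = metric_curves(
                            preds, partition, setting, aspect, graph,
                            ia=ia, weighting=_w, averaging=_avg, grid=grid, entries=es,
                        )
                        return fmax(c).value

                    curve = metric_curves(
                        preds, partition, setting, aspect, graph,
                        ia=ia, weighting=w, averaging=averaging, grid=grid, entries=entries,
                    )
                    summ = fmax(curve)
                    row = _summary_row(preds.model_tag, setting, aspect, summ)
                    if bootstrap:
                        bs = bootstrap_metric(_fmax_on, entries, B=bootstrap, level=level, seed=seed)
                        row.update(ci_low=bs.low, ci_high=bs.high, ci_level=level)
                    rows.append(row)
                if ia is not None and averaging == "micro":
                    curve = metric_curves(
                        preds, partition, setting, aspect, graph,
                        ia=ia, weighting="ia", averaging=averaging, grid=grid, entries=entries,
                    )
                    summ = smin(curve)
                    row = _summary_row(preds.model_tag, setting, aspect, summ)
                    if bootstrap:
                        def _smin_on(es):
                            c = metric_curves(
                                preds, partition, setting, aspect, graph,
                                ia=ia, weighting="ia", averaging=averaging,
                                grid=grid, entries=es,
                            )
                            return smin(c).value

                        bs = bootstrap_metric(_smin_on, entries, B=bootstrap, level=level, seed=seed)
                        row.update(ci_low=bs.low, ci_high=bs.high, ci_level=level)
                    rows.append(row)
    return pd.DataFrame(rows)


def _summary_row(model: str, setting: str, aspect: str, s: MetricSummary) -> dict:
    return {
        "model": model,
        "setting": setting,
        "aspect": aspect,
        "metric": s.metric,
        "weighting": s.weighting,
        "averaging": s.averaging,
        "value": s.value,
        "tau": s.tau,
        "coverage": s.coverage,
        "n": s.n,
    }


def challenge_score(
    preds: PredictionSet,
    partition: EvaluationPartition,
    graph: OntologyGraph,
    ia: IATable,
    grid: Sequence[float] = DEFAULT_GRID,
) -> float:
    """IA-weighted micro Fmax on NK+LK entries, averaged over the three aspects."""
    per_aspect = {}
    for aspect in ASPECTS:
        curve = metric_curves(
            preds, partition, ("NK", "LK"), aspect, graph,
            ia=ia, weighting="ia", averaging="micro", grid=grid,
        )
        per_aspect[aspect] = fmax(curve).value
    return aggregate_score(per_aspect)
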