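"""Evaluation statistics for epoch-by-epoch sleep staging.

Confusion matrices follow the convention: rows are the reference
scoring, columns the compared (predicted) scoring, stage order
W, N1, N2, N3, R.  Chance-corrected agreement uses Cohen's kappa,
kappa = (p_o - p_e) / (1 - p_e) with p_e computed from the marginals.

Metrics whose denominator is zero are reported as ``nan`` (serialized
as ``null``), never silently as 0 — with rare stages (N1 in particular)
a zero denominator is a real possibility and coercing it to 0 would
distort small-sample summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .stages import N_STAGES, STAGE_NAMES, Hypnogram, Stage

#: Marker for metrics with an empty denominator.
UNDEFINED = math.nan


def is_undefined(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


@dataclass
class ConfusionMatrix:
    """Square epoch-count matrix; ``counts[i, j]`` = reference i, compared j."""

    counts: np.ndarray
    labels: tuple[str, ...] = STAGE_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("cannot add matrices with different label sets")
        return ConfusionMatrix(self.counts + other.counts, self.labels)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion(reference: Hypnogram, compared: Hypnogram,
              labels: tuple[str, ...] = STAGE_NAMES) -> ConfusionMatrix:
    """Tally the reference-by-compared epoch counts of two equal-length hypnograms."""
    if len(reference) != len(compared):
        raise ValueError(
            f"hypnogram lengths differ: {len(reference)} vs {len(compared)}"
        )
    n = len(labels)
    idx = reference.codes * n + compared.codes
    counts = np.bincount(idx, minlength=n * n).reshape(n, n)
    return ConfusionMatrix(counts, labels)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of epochs on the diagonal (observed agreement p_o)."""
    if cm.total == 0:
        raise ValueError("accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement, kappa = (p_o - p_e) / (1 - p_e)."""
    total = cm.total
    if total == 0:
        raise ValueError("kappa undefined for an empty confusion matrix")
    p_o = np.trace(cm.counts) / total
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_e = float(row @ col) / total**2
    if p_e >= 1.0:
        raise ValueError("kappa undefined: both scorings constant and identical")
    return float((p_o - p_e) / (1.0 - p_e))


#: Landis–Koch interpretation bands, upper bound inclusive.
_KAPPA_BANDS = (
    (0.0, "Poor"),
    (0.20, "Slight"),
    (0.40, "Fair"),
    (0.60, "Moderate"),
    (0.80, "Substantial"),
    (1.0, "Almost Perfect"),
)


def kappa_band(kappa: float) -> str:
    """Landis–Koch remark for a kappa value (e.g. 0.78 -> "Substantial")."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa out of range: {kappa}")
    for upper, remark in _KAPPA_BANDS:
        if kappa <= upper:
            return remark
    return "Almost Perfect"  # unreachable; kappa <= 1 handled above


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


@dataclass
class StageMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def stage_metrics(cm: ConfusionMatrix, stage: Stage | int) -> StageMetrics:
    """One-vs-rest sensitivity/specificity/PPV/NPV for a single stage."""
    if cm.total == 0:
        raise ValueError("metrics undefined for an empty confusion matrix")
    s = int(stage)
    tp = float(cm.counts[s, s])
    fn = float(cm.counts[s].sum() - tp)
    fp = float(cm.counts[:, s].sum() - tp)
    tn = float(cm.total - tp - fn - fp)
    return StageMetrics(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def sleep_wake_metrics(cm: ConfusionMatrix) -> tuple[float, float]:
    """Sensitivity and specificity of sleep detection (sleep = any of N1..R).

    Collapsing {N1, N2, N3, R} against W makes sleep the positive class,
    so sleep sensitivity is identically the W-stage specificity and
    sleep specificity the W-stage sensitivity.
    """
    if cm.total == 0:
        raise ValueError("metrics undefined for an empty confusion matrix")
    w = int(Stage.W)
    sleep_ref = np.delete(np.arange(len(cm.labels)), w)
    tp = float(cm.counts[np.ix_(sleep_ref, sleep_ref)].sum())
    fn = float(cm.counts[sleep_ref, w].sum())
    tn = float(cm.counts[w, w])
    fp = float(cm.counts[w, sleep_ref].sum())
    return _ratio(tp, tp + fn), _ratio(tn, tn + fp)


#: Stage-collapsing schemes: 4-stage merges N1+N2; 3-stage merges all NREM.
COLLAPSE_SCHEMES: Mapping[str, tuple[tuple[int, ...], tuple[str, ...]]] = {
    "4-stage": ((0, 1, 1, 2, 3), ("W", "N1+N2", "N3", "R")),
    "3-stage": ((0, 1, 1, 1, 2), ("W", "N1+N2+N3", "R")),
}


def collapse_stages(h: Hypnogram, scheme: Literal["4-stage", "3-stage"]) -> Hypnogram:
    """Remap a 5-stage hypnogram onto a merged label set."""
    try:
        mapping, _ = COLLAPSE_SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown collapse scheme {scheme!r}") from None
    codes = np.asarray(mapping, dtype=np.int64)[h.codes]
    return Hypnogram(codes, source_id=f"{h.source_id}|{scheme}")


def collapsed_confusion(reference: Hypnogram, compared: Hypnogram,
                        scheme: Literal["4-stage", "3-stage"]) -> ConfusionMatrix:
    labels = COLLAPSE_SCHEMES[scheme][1]
    return confusion(collapse_stages(reference, scheme),
                     collapse_stages(compared, scheme), labels=labels)


def stage_specific_agreement(
    a: Hypnogram,
    b: Hypnogram,
    mode: Literal["fixed-reference", "symmetric-average"] = "fixed-reference",
) -> dict[str, float]:
    """Per-stage agreement fractions between two scorings.

    ``fixed-reference``: for each stage s, the fraction of ``a``'s
    s-epochs that ``b`` also labels s (``a`` is the reference).
    ``symmetric-average``: the mean of the two fixed-reference values
    with the roles of ``a`` and ``b`` swapped — the convention for
    human-vs-human comparisons where neither scoring is privileged.
    """
    if len(a) != len(b):
        raise ValueError("hypnogram lengths differ")

    def fixed(ref: Hypnogram, other: Hypnogram) -> np.ndarray:
        cm = confusion(ref, other).counts
        row = cm.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore"):
            return np.where(row > 0, np.diag(cm) / np.where(row > 0, row, 1), UNDEFINED)

    if mode == "fixed-reference":
        vals = fixed(a, b)
    elif mode == "symmetric-average":
        va, vb = fixed(a, b), fixed(b, a)
        # nan-propagating mean: undefined if either direction is undefined
        vals = (va + vb) / 2.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {STAGE_NAMES[i]: float(vals[i]) for i in range(N_STAGES)}


@dataclass
class ConsensusReport:
    """Agreement of an automatic scoring with a pair of manual scorings."""

    consensus_fraction: float          # epochs where the two manual scorers agree
    consensus_accuracy: float          # auto accuracy on that subset
    consensus_kappa: float
    consensus_stage_agreement: dict[str, float]
    match_at_least_one: float          # epochs where auto matches s1 or s2
    n_epochs: int
    n_consensus: int


def consensus_analysis(s1: Hypnogram, s2: Hypnogram, auto: Hypnogram) -> ConsensusReport:
    if not (len(s1) == len(s2) == len(auto)):
        raise ValueError("hypnogram lengths differ")
    n = len(s1)
    agree12 = s1.codes == s2.codes
    n_cons = int(agree12.sum())
    match_any = float(((auto.codes == s1.codes) | (auto.codes == s2.codes)).mean())
    if n_cons == 0:
        return ConsensusReport(0.0, UNDEFINED, UNDEFINED,
                               {s: UNDEFINED for s in STAGE_NAMES}, match_any, n, 0)
    ref = Hypnogram(s1.codes[agree12], source_id="consensus")
    sub = Hypnogram(auto.codes[agree12], source_id=auto.source_id)
    cm = confusion(ref, sub)
    try:
        kap = cohens_kappa(cm)
    except ValueError:
        kap = UNDEFINED
    return ConsensusReport(
        consensus_fraction=n_cons / n,
        consensus_accuracy=accuracy(cm),
        consensus_kappa=kap,
        consensus_stage_agreement=stage_specific_agreement(ref, sub, "fixed-reference"),
        match_at_least_one=match_any,
        n_epochs=n,
        n_consensus=n_cons,
    )


@dataclass
class HypnogramSummary:
    tst_min: float                 # total sleep time: 0.5 min per non-W epoch
    sleep_efficiency_pct: float    # TST / scored span
    stage_counts: dict[str, int]
    stage_percentages: dict[str, float]
    n_epochs: int


def hypnogram_summary(h: Hypnogram) -> HypnogramSummary:
    """TST, sleep efficiency and stage composition of one hypnogram.

    The efficiency denominator is the full scored span (trimmed
    recordings carry no lights-off annotation, so scored span is the
    best available stand-in for time in bed).
    """
    counts = h.counts()
    n = len(h)
    minutes_per_epoch = h.epoch_duration_s / 60.0
    tst = float((n - counts[Stage.W]) * minutes_per_epoch)
    return HypnogramSummary(
        tst_min=tst,
        sleep_efficiency_pct=100.0 * tst / (n * minutes_per_epoch),
        stage_counts={STAGE_NAMES[i]: int(counts[i]) for i in range(N_STAGES)},
        stage_percentages={STAGE_NAMES[i]: 100.0 * counts[i] / n for i in range(N_STAGES)},
        n_epochs=n,
    )


@dataclass
class MetricsReport:
    """Pooled performance of one comparison: accuracy, kappa, stage metrics."""

    accuracy: float
    kappa: float
    kappa_remark: str
    per_stage: dict[str, StageMetrics]
    sleep_sensitivity: float
    sleep_specificity: float
    n_epochs: int
    confusion: ConfusionMatrix = field(repr=False, default=None)

    def to_dict(self) -> dict:
        def clean(x):
            return None if is_undefined(x) else x

        return {
            "accuracy": clean(self.accuracy),
            "kappa": clean(self.kappa),
            "kappa_remark": self.kappa_remark,
            "per_stage": {
                s: {k: clean(v) for k, v in vars(m).items()}
                for s, m in self.per_stage.items()
            },
            "sleep_sensitivity": clean(self.sleep_sensitivity),
            "sleep_specificity": clean(self.sleep_specificity),
            "n_epochs": self.n_epochs,
            "confusion": self.confusion.counts.tolist() if self.confusion is not None else None,
        }


def evaluate(cm: ConfusionMatrix) -> MetricsReport:
    """Full metrics report from a pooled 5-stage confusion matrix."""
    kap = cohens_kappa(cm)
    sens, spec = sleep_wake_metrics(cm)
    return MetricsReport(
        accuracy=accuracy(cm),
        kappa=kap,
        kappa_remark=kappa_band(kap),
        per_stage={STAGE_NAMES[int(s)]: stage_metrics(cm, s) for s in Stage},
        sleep_sensitivity=sens,
        sleep_specificity=spec,
        n_epochs=cm.total,
        confusion=cm,
    )


def groupwise_evaluate(
    per_recording: Mapping[str, ConfusionMatrix],
    metadata: Mapping[str, Mapping],
    ahi_threshold: float = 1.0,
) -> dict[str, MetricsReport]:
    """Pool per-recording confusion matrices by clinical group.

    Groups: recruitment flag (``SDB`` vs ``control``) and PSG-quantified
    OSA status (``ahi>=1`` vs ``ahi<1``; a recording with AHI exactly at
    the threshold goes to the >= group), plus the overall pool.
    """
    pools: dict[str, ConfusionMatrix | None] = {
        "all": None, "SDB": None, "control": None, "ahi>=1": None, "ahi<1": None,
    }

    def add(key: str, cm: ConfusionMatrix) -> None:
        pools[key] = cm if pools[key] is None else pools[key] + cm

    for rec_id, cm in per_recording.items():
        if rec_id not in metadata:
            raise KeyError(f"no metadata for recording {rec_id!r}")
        meta = metadata[rec_id]
        add("all", cm)
        add("SDB" if meta["group"] == "SDB" else "control", cm)
        add("ahi>=1" if meta["ahi"] >= ahi_threshold else "ahi<1", cm)

    return {k: evaluate(cm) for k, cm in pools.items() if cm is not None}


@dataclass
class PairwiseAgreement:
    percent_agreement: float
    kappa: float
    remark: str
    per_stage: dict[str, float]


def agreement_table(
    scorings: Mapping[str, Hypnogram],
    pairs: Sequence[tuple[str, str]] | None = None,
    auto_ids: frozenset[str] | set[str] = frozenset(),
) -> dict[str, PairwiseAgreement]:
    """Pairwise rater-agreement table over a set of scorings of one record set.

    For human-vs-human pairs the per-stage agreement is the symmetric
    average; for pairs involving an automatic scoring (``auto_ids``)
    the manual scoring is the fixed reference.
    """
    ids = list(scorings)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    out: dict[str, PairwiseAgreement] = {}
    for a, b in pairs:
        ha, hb = scorings[a], scorings[b]
        if b in auto_ids and a not in auto_ids:
            mode, ref, other = "fixed-reference", ha, hb
        elif a in auto_ids and b not in auto_ids:
            mode, ref, other = "fixed-reference", hb, ha
        else:
            mode, ref, other = "symmetric-average", ha, hb
        cm = confusion(ref, other)
        kap = cohens_kappa(cm)
        out[f"{a} vs {b}"] = PairwiseAgreement(
            percent_agreement=100.0 * accuracy(cm),
            kappa=kap,
            remark=kappa_band(kap),
            per_stage=stage_specific_agreement(ref, other, mode),
        )
    return out
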