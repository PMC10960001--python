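"""Hierarchical chemical-taxonomy framework.

Four sequential random-forest classifiers answer one structural question
each — (1) blank vs epimer, (2) monosaccharide vs cerebroside, (3) saturated
vs unsaturated ceramide, (4) glucosyl vs galactosyl — and two support-vector
regressors estimate the ceramide chain length for the hexose chosen at stage
4.  A sample is routed stage by stage; the per-stage class probabilities,
the routing path and the assembled nomenclature form the prediction.  Because
every stage answers a *conditional* question, each sub-model trains on the
label-filtered subset along its routing path: stage 2 never sees blanks,
stages 3-4 and the regressors train on cerebrosides only.

Forward prediction is the leave-one-cerebroside-out protocol: the 60 spectra
of one cerebroside class are removed entirely, models are trained on the
rest, and the held-out spectra are routed through the cascade.  A spectrum
counts as correct overall only if every applicable stage is correct.  The
chain-length regressor then extrapolates/interpolates to the unseen class.

Concentration transfer trains the cascade at the top concentration only and
probes it with an excluded class generated across lower decades.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

from ._sk import make_screened_svr
from .errors import SchemaError, TrainingError, ValidationError
from .io import AnalyteLabel

__all__ = [
    "TaxonomyHyperparams",
    "TaxonomyModel",
    "TaxonomyPrediction",
    "ConsensusPrediction",
    "Protocol",
    "ConfusionCounts",
    "ClassificationMetrics",
    "train_taxonomy",
    "predict_sample",
    "predict_table",
    "predict_majority",
    "forward_prediction",
    "concentration_transfer",
    "metrics",
    "embed_2d",
    "feature_columns",
]

#: Ordered stage names and their (positive, negative) class labels.
STAGES = (
    ("stage1", ("epimer", "blank")),
    ("stage2", ("cerebroside", "monosaccharide")),
    ("stage3", ("saturated", "unsaturated")),
    ("stage4", ("glc", "gal")),
)


def feature_columns(df: pd.DataFrame) -> list:
    """The 95 feature columns of a feature table (``pNN_attr`` layout)."""
    cols = [c for c in df.columns
            if len(c) > 4 and c.startswith("p") and c[1:3].isdigit()
            and c[3] == "_"]
    if not cols:
        raise SchemaError("no feature columns (pNN_attr) found")
    return cols


@dataclass(frozen=True)
class TaxonomyHyperparams:
    """Model hyperparameters for the cascade.

    Random forests: 1000 trees, sqrt(features) per split, depth 10, no
    splitting of subsets smaller than 5.  Chain-length SVRs: linear kernel
    on standardized features after univariate screening to the
    ``chain_features`` most chain-correlated features, C = 1, epsilon =
    0.1 carbons.  The chain response is linear in the band intensities, so
    a linear kernel extrapolates to unseen chain lengths; the screening
    gives exactly zero weight to bands that carry concentration rather
    than chain information, keeping predictions stable when the cascade is
    probed far below the training concentration.
    """

    n_trees: int = 1000
    max_depth: int = 10
    min_samples_split: int = 5
    max_features: str = "sqrt"
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    chain_features: int = 8


@dataclass
class TaxonomyModel:
    """The six trained sub-models plus feature schema and metadata."""

    stages: dict                 # stage name -> fitted classifier
    regressors: dict             # hexose -> fitted regressor (or absent)
    schema: list                 # feature column names
    hyperparams: TaxonomyHyperparams
    seed: int
    metadata: dict = field(default_factory=dict)

    def check_schema(self, cols) -> None:
        if list(cols) != list(self.schema):
            raise SchemaError("feature columns do not match model schema")


@dataclass
class TaxonomyPrediction:
    """Routing result for one spectrum."""

    probabilities: dict          # stage -> {class: p}; pairs sum to 1
    path: list                   # routed class per visited stage
    chain_raw: float | None
    chain_rounded: int | None
    nomenclature: str
    low_confidence: list         # stages whose winning probability <= 0.5


@dataclass
class ConsensusPrediction:
    """Majority-vote consensus over replicates."""

    path: list
    nomenclature: str
    chain_mean: float | None
    chain_sd: float | None
    chain_rounded: int | None
    ties: list                   # stages resolved by mean probability
    low_confidence: list
    table: pd.DataFrame          # one row per replicate


@dataclass(frozen=True)
class Protocol:
    """Training/evaluation protocol for forward prediction.

    ``mode``: ``"stratified"`` draws a stratified 80% training subsample per
    iteration (the default protocol); ``"kfold5"`` uses 5-fold stratified
    splits, cycling through folds across iterations.
    """

    mode: str = "stratified"
    iterations: int = 100
    train_fraction: float = 0.8

    def __post_init__(self):
        if self.mode not in ("stratified", "kfold5"):
            raise ValidationError(f"unknown protocol mode {self.mode!r}")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")

    @classmethod
    def mini(cls) -> "Protocol":
        """Reduced protocol (10 iterations) for desk-scale runs."""
        return cls(iterations=10)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _stage_frames(df: pd.DataFrame):
    """(stage name, subset, binary target) triples per the routing path."""
    is_blank = df["category"] == "blank"
    non_blank = df[~is_blank]
    cer = df[df["category"] == "cerebroside"]
    yield "stage1", df, np.where(is_blank, "blank", "epimer")
    yield "stage2", non_blank, np.where(
        non_blank["category"] == "cerebroside", "cerebroside",
        "monosaccharide")
    yield "stage3", cer, np.where(
        cer["saturation"].astype(float) > 0, "unsaturated", "saturated")
    yield "stage4", cer, cer["hexose"].to_numpy()


def train_taxonomy(df: pd.DataFrame,
                   hp: TaxonomyHyperparams | None = None,
                   seed: int = 0) -> TaxonomyModel:
    """Train the four classifier stages and the two chain-length regressors.

    ``df`` is a feature table (95 ``pNN_attr`` columns plus the label
    columns ``category``, ``hexose``, ``saturation``, ``chain_length``).
    Raises :class:`TrainingError` naming the stage if any stage sees only
    one class.  Regressors are trained per hexose on the matching
    cerebrosides (target: chain length); a hexose absent from the training
    set simply has no regressor.
    """
    if hp is None:
        hp = TaxonomyHyperparams()
    cols = feature_columns(df)
    stages = {}
    counts = {}
    for name, sub, target in _stage_frames(df):
        classes = np.unique(target)
        if len(classes) < 2:
            raise TrainingError(
                f"{name}: training data contains a single class "
                f"({classes.tolist()})"
            )
        clf = RandomForestClassifier(
            n_estimators=hp.n_trees,
            max_depth=hp.max_depth,
            min_samples_split=hp.min_samples_split,
            max_features=hp.max_features,
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(sub[cols].to_numpy(), target)
        stages[name] = clf
        counts[name] = len(sub)

    regressors = {}
    cer = df[df["category"] == "cerebroside"]
    for hexose in ("glc", "gal"):
        sub = cer[cer["hexose"] == hexose]
        if len(sub) == 0:
            continue
        reg = make_screened_svr(hp.svr_c, hp.svr_epsilon,
                                k=hp.chain_features)
        reg.fit(sub[cols].to_numpy(),
                sub["chain_length"].astype(float).to_numpy())
        regressors[hexose] = reg
        counts[f"reg_{hexose}"] = len(sub)
        counts[f"chain_range_{hexose}"] = (
            int(sub["chain_length"].min()), int(sub["chain_length"].max())
        )

    return TaxonomyModel(
        stages=stages, regressors=regressors, schema=cols,
        hyperparams=hp, seed=seed,
        metadata={"training_rows": counts},
    )


# ---------------------------------------------------------------------------
# prediction / routing
# ---------------------------------------------------------------------------

def _stage_proba(clf, X) -> dict:
    proba = clf.predict_proba(X)
    return {c: proba[:, i] for i, c in enumerate(clf.classes_)}


def predict_table(df_or_X, model: TaxonomyModel) -> pd.DataFrame:
    """Route a batch of samples; one row per sample.

    Columns: per-stage probabilities (``stage1_blank`` ...), the routed
    class per stage (NaN once a sample leaves the path), ``chain_raw``,
    ``chain_rounded``, ``nomenclature`` and ``low_confidence`` (the
    semicolon-joined stages whose winning probability was <= 0.5).
    """
    if isinstance(df_or_X, pd.DataFrame):
        X = df_or_X[model.schema].to_numpy()
    else:
        X = np.asarray(df_or_X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(model.schema):
            raise SchemaError(
                f"expected {len(model.schema)} features, got {X.shape[1]}"
            )
    n = X.shape[0]
    out = pd.DataFrame(index=range(n))
    active = np.ones(n, dtype=bool)       # still on the cerebroside path
    routed = {}
    low_conf = [[] for _ in range(n)]

    for name, (pos, neg) in STAGES:
        proba = _stage_proba(model.stages[name], X)
        for cls, p in proba.items():
            out[f"{name}_{cls}"] = p
        winner = np.where(proba[pos] >= proba[neg], pos, neg)
        win_p = np.maximum(proba[pos], proba[neg])
        routed[name] = np.where(active, winner, None)
        for i in np.flatnonzero(active & (win_p <= 0.5)):
            low_conf[i].append(name)
        out[f"{name}_class"] = routed[name]
        # samples routed off the cerebroside path stop at this stage
        if name == "stage1":
            active = active & (winner == "epimer")
        elif name == "stage2":
            active = active & (winner == "cerebroside")

    chain_raw = np.full(n, np.nan)
    for hexose, reg in model.regressors.items():
        mask = np.asarray(
            [routed["stage4"][i] == hexose for i in range(n)]
        )
        if mask.any():
            chain_raw[mask] = reg.predict(X[mask])
    out["chain_raw"] = chain_raw
    out["chain_rounded"] = np.where(
        np.isnan(chain_raw), np.nan, np.round(chain_raw)
    )

    names = []
    for i in range(n):
        if routed["stage1"][i] == "blank":
            names.append("MPBA blank")
        elif routed["stage2"][i] == "monosaccharide":
            names.append("monosaccharide")
        else:
            stem = "GlcCer" if routed["stage4"][i] == "glc" else "GalCer"
            sat = ":1" if routed["stage3"][i] == "unsaturated" else ""
            if np.isnan(chain_raw[i]):
                names.append(f"{stem}?{sat}")
            else:
                names.append(f"{stem}{int(round(chain_raw[i]))}{sat}")
    out["nomenclature"] = names
    out["low_confidence"] = [";".join(l) for l in low_conf]
    return out


def predict_sample(fv, model: TaxonomyModel) -> TaxonomyPrediction:
    """Route one feature vector through the cascade.

    Probabilities of every visited stage are recorded; a stage whose winning
    probability is <= 0.5 is flagged low-confidence but never halts routing.
    """
    row = predict_table(fv, model).iloc[0]
    probabilities = {}
    path = []
    for name, (pos, neg) in STAGES:
        if row[f"{name}_class"] is None:
            break
        probabilities[name] = {
            pos: float(row[f"{name}_{pos}"]),
            neg: float(row[f"{name}_{neg}"]),
        }
        path.append(row[f"{name}_class"])
    chain_raw = None if np.isnan(row["chain_raw"]) else float(row["chain_raw"])
    return TaxonomyPrediction(
        probabilities=probabilities,
        path=path,
        chain_raw=chain_raw,
        chain_rounded=None if chain_raw is None else int(round(chain_raw)),
        nomenclature=row["nomenclature"],
        low_confidence=row["low_confidence"].split(";")
        if row["low_confidence"] else [],
    )


def predict_majority(df_or_X, model: TaxonomyModel) -> ConsensusPrediction:
    """Majority-vote consensus over replicate spectra of one sample.

    The consensus class at each stage is the modal routed class among the
    replicates reaching that stage; an exact tie is resolved toward the
    class with the larger mean probability and flagged.  The consensus chain
    length is the mean of the raw regressor estimates of the replicates
    routed to the consensus hexose, reported mean +- SD and then rounded.
    """
    table = predict_table(df_or_X, model)
    if len(table) < 1:
        raise ValidationError("need at least one replicate")
    path = []
    ties = []
    low_conf = sorted({
        s for row in table["low_confidence"] if row for s in row.split(";")
    })
    for name, (pos, neg) in STAGES:
        routed = [c for c in table[f"{name}_class"] if c is not None]
        if not routed:
            break
        votes = Counter(routed)
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            # tie: larger mean probability wins
            mean_p = {
                cls: table.loc[table[f"{name}_class"].notna(),
                               f"{name}_{cls}"].mean()
                for cls, _ in top[:2]
            }
            winner = max(mean_p, key=mean_p.get)
            ties.append(name)
        else:
            winner = top[0][0]
        path.append(winner)
        if name == "stage1" and winner == "blank":
            break
        if name == "stage2" and winner == "monosaccharide":
            break

    chain_mean = chain_sd = chain_rounded = None
    nomenclature = "MPBA blank"
    if path and path[0] == "epimer":
        nomenclature = "monosaccharide"
        if len(path) >= 4:
            hexose = path[3]
            sel = table[f"stage4_class"] == hexose
            raws = table.loc[sel, "chain_raw"].dropna()
            if len(raws):
                chain_mean = float(raws.mean())
                chain_sd = float(raws.std(ddof=1)) if len(raws) > 1 else 0.0
                chain_rounded = int(round(chain_mean))
            stem = "GlcCer" if hexose == "glc" else "GalCer"
            sat = ":1" if path[2] == "unsaturated" else ""
            chain_s = "?" if chain_rounded is None else str(chain_rounded)
            nomenclature = f"{stem}{chain_s}{sat}"
    return ConsensusPrediction(
        path=path, nomenclature=nomenclature,
        chain_mean=chain_mean, chain_sd=chain_sd,
        chain_rounded=chain_rounded,
        ties=ties, low_confidence=low_conf, table=table,
    )


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------

def _true_stage_classes(label: AnalyteLabel) -> dict:
    truth = {"stage1": "blank" if label.category == "blank" else "epimer"}
    if label.category != "blank":
        truth["stage2"] = ("cerebroside"
                          if label.category == "cerebroside"
                          else "monosaccharide")
    if label.category == "cerebroside":
        truth["stage3"] = "unsaturated" if label.saturation else "saturated"
        truth["stage4"] = label.hexose
    return truth


def _score_routing(table: pd.DataFrame, label: AnalyteLabel) -> dict:
    """Per-stage and overall correctness of a routed batch.

    Stage accuracy is scored among the samples reaching that stage; the
    overall score demands every applicable stage correct per sample.
    """
    truth = _true_stage_classes(label)
    n = len(table)
    result = {}
    overall = np.ones(n, dtype=bool)
    for name, _ in STAGES:
        if name not in truth:
            break
        routed = table[f"{name}_class"]
        reached = routed.notna()
        correct = (routed == truth[name]) & reached
        result[name] = float(correct[reached].mean()) if reached.any() \
            else 0.0
        overall &= correct.to_numpy()
    result["overall"] = float(overall.mean())
    return result


@dataclass
class HoldOutReport:
    """Forward-prediction result for one held-out cerebroside."""

    held_out: str
    stage_accuracy: dict          # stage -> mean accuracy over iterations
    overall_accuracy: float
    chain_mean: float | None
    chain_sd: float | None
    chain_abs_difference: float | None
    chain_extrapolated: bool
    iterations: pd.DataFrame      # per-iteration accuracies


def forward_prediction(df: pd.DataFrame, held_out,
                       protocol: Protocol | None = None,
                       seed: int = 0,
                       hp: TaxonomyHyperparams | None = None
                       ) -> HoldOutReport:
    """Leave-one-cerebroside-out forward prediction.

    Removes every spectrum of ``held_out`` (an :class:`AnalyteLabel` or its
    nomenclature string), trains the cascade on (a stratified subsample of)
    the remainder per iteration, and routes the held-out spectra.  The
    chain-length report is flagged ``extrapolated`` when the true chain
    length falls outside the matched regressor's training range (the
    regressor then cannot be expected to reach it).
    """
    if protocol is None:
        protocol = Protocol.mini()
    if isinstance(held_out, str):
        held_out = AnalyteLabel.from_nomenclature(held_out)
    if held_out.category != "cerebroside":
        raise ValidationError("held-out class must be a cerebroside")
    name = held_out.nomenclature()
    mask = df["analyte"] == name
    if not mask.any():
        raise ValidationError(f"held-out class {name} absent from dataset")
    test = df[mask]
    rest = df[~mask]

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    rows = []
    chain_raws = []
    extrapolated = False
    strata = rest["analyte"].to_numpy()
    if protocol.mode == "kfold5":
        folds = list(StratifiedKFold(
            n_splits=5, shuffle=True, random_state=int(rng.integers(2**31))
        ).split(rest, strata))
    for it in range(protocol.iterations):
        sub_seed = int(rng.integers(2**31))
        if protocol.mode == "stratified":
            train_idx, _ = train_test_split(
                np.arange(len(rest)),
                train_size=protocol.train_fraction,
                stratify=strata, random_state=sub_seed,
            )
        else:
            train_idx, _ = folds[it % len(folds)]
        train = rest.iloc[train_idx]
        model = train_taxonomy(train, hp, seed=sub_seed)
        table = predict_table(test, model)
        scores = _score_routing(table, held_out)
        scores["iteration"] = it
        rows.append(scores)
        # chain estimates from the truth-matched regressor
        reg = model.regressors.get(held_out.hexose)
        if reg is not None:
            chain_raws.append(
                reg.predict(test[model.schema].to_numpy())
            )
            lo, hi = model.metadata["training_rows"][
                f"chain_range_{held_out.hexose}"
            ]
            extrapolated |= not (lo <= held_out.chain_length <= hi)

    iters = pd.DataFrame(rows)
    stage_acc = {
        s: float(iters[s].mean()) for s, _ in STAGES if s in iters
    }
    chain_mean = chain_sd = chain_diff = None
    if chain_raws:
        pooled = np.concatenate(chain_raws)
        chain_mean = float(pooled.mean())
        chain_sd = float(pooled.std(ddof=1))
        chain_diff = abs(round(chain_mean) - held_out.chain_length)
    return HoldOutReport(
        held_out=name,
        stage_accuracy=stage_acc,
        overall_accuracy=float(iters["overall"].mean()),
        chain_mean=chain_mean,
        chain_sd=chain_sd,
        chain_abs_difference=chain_diff,
        chain_extrapolated=extrapolated,
        iterations=iters,
    )


def concentration_transfer(train_df: pd.DataFrame,
                           probe_df: pd.DataFrame,
                           probe_label,
                           seed: int = 0,
                           hp: TaxonomyHyperparams | None = None
                           ) -> pd.DataFrame:
    """Probe a cascade trained at one concentration with spectra of an
    excluded class across lower concentrations.

    ``train_df`` must not contain the probe class; ``probe_df`` carries a
    ``concentration_M`` column.  Returns one row per concentration with the
    per-stage and overall accuracies, the consensus chain length and its
    absolute difference from truth.
    """
    if isinstance(probe_label, str):
        probe_label = AnalyteLabel.from_nomenclature(probe_label)
    name = probe_label.nomenclature()
    if (train_df["analyte"] == name).any():
        raise ValidationError(f"probe class {name} present in training data")
    model = train_taxonomy(train_df, hp, seed=seed)
    rows = []
    for conc, group in probe_df.groupby("concentration_M", sort=False):
        table = predict_table(group, model)
        scores = _score_routing(table, probe_label)
        consensus = predict_majority(group, model)
        row = {"concentration_M": float(conc), "n": len(group), **scores}
        row["chain_mean"] = consensus.chain_mean
        row["chain_sd"] = consensus.chain_sd
        row["chain_abs_difference"] = (
            None if consensus.chain_rounded is None
            else abs(consensus.chain_rounded - probe_label.chain_length)
        )
        row["predicted"] = consensus.nomenclature
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values("concentration_M", ascending=False,
                           ignore_index=True)


# ---------------------------------------------------------------------------
# metrics and embedding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    true_positive: int
    false_positive: int
    true_negative: int
    false_negative: int

    def __post_init__(self):
        for f in ("true_positive", "false_positive", "true_negative",
                  "false_negative"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be >= 0")


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy, precision, recall and F1.  A metric whose denominator is
    zero is None and listed in ``undefined`` rather than raising."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    undefined: tuple = ()


def metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Standard binary classification metrics from confusion counts."""
    undefined = []
    total = (c.true_positive + c.false_positive + c.true_negative
             + c.false_negative)
    accuracy = ((c.true_positive + c.true_negative) / total
                if total else None)
    if total == 0:
        undefined.append("accuracy")
    pdenom = c.true_positive + c.false_positive
    precision = c.true_positive / pdenom if pdenom else None
    if not pdenom:
        undefined.append("precision")
    rdenom = c.true_positive + c.false_negative
    recall = c.true_positive / rdenom if rdenom else None
    if not rdenom:
        undefined.append("recall")
    if precision is not None and recall is not None \
            and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
        undefined.append("f1")
    return ClassificationMetrics(accuracy, precision, recall, f1,
                                 tuple(undefined))


def embed_2d(X, method: str = "tsne", perplexity: float = 30.0,
             exaggeration: float = 1.0, pca_components: int = 15,
             seed: int = 0) -> np.ndarray:
    """2-D embedding for visual QC of the SERS molecular space.

    t-SNE (perplexity 30, exaggeration 1) after PCA compression to 15
    components; ``method="pca"`` gives the deterministic 2-component PCA
    view instead.  t-SNE requires at least ``3 * perplexity`` samples.
    """
    X = np.asarray(X, float)
    if method == "pca":
        return PCA(n_components=2, random_state=seed).fit_transform(
            StandardScaler().fit_transform(X)
        )
    if method != "tsne":
        raise ValidationError(f"unknown embedding method {method!r}")
    if X.shape[0] < 3 * perplexity:
        raise ValidationError(
            f"t-SNE with perplexity {perplexity:g} needs >= "
            f"{int(3 * perplexity)} samples, got {X.shape[0]}"
        )
    Xs = StandardScaler().fit_transform(X)
    k = min(pca_components, Xs.shape[1], Xs.shape[0])
    Xc = PCA(n_components=k, random_state=seed).fit_transform(Xs)
    return TSNE(
        n_components=2, perplexity=perplexity,
        early_exaggeration=max(exaggeration, 1.0),
        init="pca", random_state=seed,
    ).fit_transform(Xc)
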