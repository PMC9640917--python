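"""Evaluation protocol: stratified 5-fold CV, threshold metrics, AUC, Z test.

Conventions mirror the study protocol this package emulates:

* stratified k-fold (default k=5, i.e. 4:1 train:validation) within the
  record subset a branch can see;
* accuracy / sensitivity / precision / F1 at the fixed 50% threshold, with a
  positive call requiring probability strictly greater than 0.5;
* AUC as the Mann-Whitney statistic (ties count 1/2);
* unpaired Z test on two AUCs with Hanley-McNeil standard errors;
* fold metrics aggregated as mean +/- sample standard deviation (ddof=1);
* validation folds always consist of original (never augmented) records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold

from .fusion import FusionConfig, fuse_branches, joint_update
from .models import BASELINE_KINDS, BranchConfig, build_baseline, build_single_branch
from .preprocessing import CT, MODALITY_CHANNELS, MRI
from .seeds import derive_seed
from .training import (
    AugmentationPolicy,
    TrainingConfig,
    end_to_end_epochs_for_parity,
    finetune_classifier,
    matched_end_to_end_config,
    pretrain_embedding,
    records_to_arrays,
    train_end_to_end,
)

METRIC_NAMES = ("accuracy", "sensitivity", "precision", "f1", "auc")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """Stratified k-fold assignment over lesion ids."""

    ids: list
    labels: np.ndarray
    folds: list  # list of np arrays of indices (validation sets)
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def fold_ids(self, i):
        return [self.ids[j] for j in self.folds[i]]

    def train_val_indices(self, i):
        val = self.folds[i]
        train = np.setdiff1d(np.arange(len(self.ids)), val)
        return train, val


def stratified_kfold(records, k: int = 5, seed: int = 0) -> FoldSplit:
    """Label-stratified partition of records into k validation folds."""
    ids = [r.lesion_id for r in records]
    y = np.array([r.label for r in records])
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [val for _, val in skf.split(np.zeros(len(y)), y)]
    return FoldSplit(ids=ids, labels=y, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_metrics(labels, probabilities, threshold: float = 0.5) -> dict:
    """Accuracy / sensitivity / precision / F1 at a fixed threshold.

    A positive call requires probability strictly greater than ``threshold``.
    With no positive predictions, precision and F1 are defined as 0 and
    ``degenerate`` is flagged.
    """
    y = np.asarray(labels).ravel()
    p = np.asarray(probabilities, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have the same length")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be binary")
    pred = (p > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    accuracy = (tp + tn) / y.size
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    degenerate = (tp + fp) == 0
    precision = 0.0 if degenerate else tp / (tp + fp)
    f1 = 0.0 if (precision + sensitivity) == 0 else 2 * precision * sensitivity / (precision + sensitivity)
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "precision": precision,
        "f1": f1,
        "degenerate": degenerate,
        "counts": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


def roc_auc(labels, scores) -> float:
    """AUC as the Mann-Whitney statistic: P(score+ > score-) with ties = 1/2."""
    y = np.asarray(labels).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Closed-form standard error of an AUC from counts alone."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("counts must be >= 1")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return float(np.sqrt(var))


def auc_z_test(auc1, n_pos1, n_neg1, auc2, n_pos2, n_neg2):
    """Unpaired Z comparison of two AUCs; returns (Z, two-sided p)."""
    for a in (auc1, auc2):
        if not 0.0 < a < 1.0:
            raise ValueError("AUC values must lie strictly inside (0, 1)")
    se1 = hanley_mcneil_se(auc1, n_pos1, n_neg1)
    se2 = hanley_mcneil_se(auc2, n_pos2, n_neg2)
    z = (auc2 - auc1) / np.sqrt(se1**2 + se2**2)
    p = 2.0 * float(norm.sf(abs(z)))
    return float(z), p


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentSpec:
    branch: str = "CT"  # 'CT', 'MRI', or 'double'
    network: str = "mcat"  # 'mcat' or one of the baseline kinds
    mode: str = "two_stage"  # 'two_stage' or 'end_to_end'

    def __post_init__(self):
        if self.branch not in (CT, MRI, "double"):
            raise ValueError(f"bad branch: {self.branch}")
        if self.network != "mcat" and self.network not in BASELINE_KINDS:
            raise ValueError(f"bad network: {self.network}")
        if self.mode not in ("two_stage", "end_to_end"):
            raise ValueError(f"bad mode: {self.mode}")
        if self.network != "mcat" and self.mode == "two_stage":
            raise ValueError("two-stage training applies to the embedding-structured network only")

    @property
    def descriptor(self) -> str:
        return f"{self.branch}/{self.network}/{self.mode}"


@dataclass
class HarnessConfig:
    """Shared per-experiment training settings for the CV harness."""

    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    pretrain: TrainingConfig = field(default_factory=lambda: TrainingConfig(stage="pretrain"))
    finetune: TrainingConfig = field(default_factory=lambda: TrainingConfig(stage="finetune"))
    fusion: FusionConfig = field(default_factory=FusionConfig)
    branch_overrides: dict = field(default_factory=dict)  # kwargs for BranchConfig
    k: int = 5


@dataclass
class MetricsReport:
    """Per-fold metric rows plus mean/SD aggregation, one per experiment."""

    rows: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        out = []
        for desc, grp in self.rows.groupby("experiment", sort=False):
            agg = {"experiment": desc}
            for m in METRIC_NAMES:
                agg[f"{m}_mean"] = grp[m].mean()
                agg[f"{m}_sd"] = grp[m].std(ddof=1)
            out.append(agg)
        return pd.DataFrame(out)

    def mean(self, experiment: str, metric: str) -> float:
        grp = self.rows[self.rows["experiment"] == experiment]
        return float(grp[metric].mean())

    def to_csv(self, path):
        self.rows.to_csv(path, index=False)

    def to_markdown(self) -> str:
        agg = self.aggregate()
        lines = ["| experiment | " + " | ".join(METRIC_NAMES) + " |",
                 "|---" * (len(METRIC_NAMES) + 1) + "|"]
        for _, r in agg.iterrows():
            cells = [
                f"{r[f'{m}_mean'] * (100 if m != 'auc' else 1):.2f} ± "
                f"{r[f'{m}_sd'] * (100 if m != 'auc' else 1):.2f}"
                for m in METRIC_NAMES
            ]
            lines.append("| " + r["experiment"] + " | " + " | ".join(cells) + " |")
        return "\n".join(lines)


def _assert_original(records):
    bad = [r.lesion_id for r in records if r.origin != "original"]
    if bad:
        raise AssertionError(f"augmented records leaked into validation: {bad}")


def _branch_records(records, modality):
    return [r for r in records if r.availability in (modality, "both")]


def _train_single(modality, network, mode, train_records, cfg: HarnessConfig, seed):
    if network == "mcat":
        bcfg = BranchConfig(modality=modality, **cfg.branch_overrides)
        net = build_single_branch(bcfg, seed=derive_seed(seed, "init", modality, network))
    else:
        net = build_baseline(
            network,
            len(MODALITY_CHANNELS[modality]),
            seed=derive_seed(seed, "init", modality, network),
        )
    train_seed = derive_seed(seed, "train", modality, network, mode)
    if mode == "two_stage":
        pre = replace(cfg.pretrain, seed=train_seed)
        fine = replace(cfg.finetune, seed=derive_seed(seed, "finetune", modality, network))
        pretrain_embedding(net, train_records, cfg.policy, pre)
        finetune_classifier(net, train_records, fine)
    else:
        epochs = end_to_end_epochs_for_parity(
            len(train_records), cfg.policy, cfg.pretrain, cfg.finetune
        )
        e2e = replace(
            matched_end_to_end_config(cfg.pretrain, epochs), seed=train_seed
        )
        train_end_to_end(net, train_records, cfg.policy, e2e, modality=modality)
    return net


def _fold_metrics(y_val, probs) -> dict:
    cm = confusion_metrics(y_val, probs)
    return {
        "accuracy": cm["accuracy"],
        "sensitivity": cm["sensitivity"],
        "precision": cm["precision"],
        "f1": cm["f1"],
        "auc": roc_auc(y_val, probs),
    }


def run_single_branch_cv(records, modality, network, mode, cfg: HarnessConfig, seed):
    """5-fold CV of one single-branch experiment; returns per-fold rows."""
    subset = _branch_records(records, modality)
    split = stratified_kfold(subset, k=cfg.k, seed=derive_seed(seed, "fold", modality))
    rows = []
    for i in range(split.k):
        tr_idx, va_idx = split.train_val_indices(i)
        train = [subset[j] for j in tr_idx]
        val = [subset[j] for j in va_idx]
        _assert_original(val)
        net = _train_single(
            modality, network, mode, train, cfg, derive_seed(seed, "fit", modality, str(i))
        )
        x_val, y_val = records_to_arrays(val, modality)
        probs = net.predict_proba(x_val)
        rows.append({"fold": i, "n_val": len(val), **_fold_metrics(y_val, probs)})
    return rows


def run_double_branch_cv(records, network, mode, cfg: HarnessConfig, seed):
    """5-fold CV over mixed lesions with the fused double-branch model.

    Folds stratify the both-modality subset; each branch trains on its
    single-modality records plus the mixed training fold, then the fused
    model is jointly updated on the mixed training fold.
    """
    mixed = [r for r in records if r.availability == "both"]
    split = stratified_kfold(mixed, k=cfg.k, seed=derive_seed(seed, "fold", "double"))
    ct_only = [r for r in records if r.availability == CT]
    mri_only = [r for r in records if r.availability == MRI]
    rows = []
    for i in range(split.k):
        tr_idx, va_idx = split.train_val_indices(i)
        mixed_train = [mixed[j] for j in tr_idx]
        val = [mixed[j] for j in va_idx]
        _assert_original(val)
        fold_seed = derive_seed(seed, "fit", "double", str(i))
        ct_net = _train_single(CT, network, mode, ct_only + mixed_train, cfg, fold_seed)
        mri_net = _train_single(MRI, network, mode, mri_only + mixed_train, cfg, fold_seed)
        fcfg = replace(cfg.fusion, seed=derive_seed(seed, "fuse", str(i)))
        model = fuse_branches(ct_net, mri_net, fcfg)
        y_val = np.array([r.label for r in val])
        # paired single-branch scores on the same validation lesions,
        # taken before the joint update (the pure single-branch models)
        p_ct = np.array([model.branch_probability(r, CT) for r in val])
        p_mr = np.array([model.branch_probability(r, MRI) for r in val])
        model = joint_update(model, mixed_train, fcfg)
        probs, _ = model.predict_many(val)
        rows.append(
            {
                "fold": i,
                "n_val": len(val),
                **_fold_metrics(y_val, probs),
                "ct_alone_auc": roc_auc(y_val, p_ct),
                "mri_alone_auc": roc_auc(y_val, p_mr),
            }
        )
    return rows


def run_cv_experiment(records, grid, seed: int, cfg: HarnessConfig | None = None) -> MetricsReport:
    """Run every experiment in ``grid`` with the shared harness settings."""
    cfg = cfg or HarnessConfig()
    all_rows = []
    for exp in grid:
        if exp.branch == "double":
            rows = run_double_branch_cv(records, exp.network, exp.mode, cfg, seed)
        else:
            rows = run_single_branch_cv(records, exp.branch, exp.network, exp.mode, cfg, seed)
        for r in rows:
            all_rows.append({"experiment": exp.descriptor, **r})
    return MetricsReport(rows=pd.DataFrame(all_rows))


# ---------------------------------------------------------------------------
# embedding projection (separability visualisation)
# ---------------------------------------------------------------------------

def project_embeddings(embeddings, labels, method: str = "pca", seed: int = 0):
    """Deterministic 2D projection of embeddings; returns (coords, labels)."""
    emb = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels).ravel()
    if emb.shape[0] != y.shape[0]:
        raise ValueError("embeddings and labels length mismatch")
    if emb.shape[0] < 3:
        raise ValueError("need at least 3 points to project")
    if method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, random_state=seed).fit_transform(emb)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, (emb.shape[0] - 1) / 3.0)
        coords = TSNE(
            n_components=2, random_state=seed, init="pca", perplexity=perplexity
        ).fit_transform(emb)
    else:
        raise ValueError(f"unknown projection method: {method}")
    return np.asarray(coords, dtype=np.float64), y


def save_projection(coords, labels, csv_path, fig_path=None):
    df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "label": labels})
    df.to_csv(csv_path, index=False)
    if fig_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for lab, color in ((0, "tab:blue"), (1, "tab:orange")):
            m = labels == lab
            ax.scatter(coords[m, 0], coords[m, 1], s=12, c=color, label=f"MVI {'+' if lab else '-'}")
        ax.legend()
        ax.set_xlabel("dim 1")
        ax.set_ylabel("dim 2")
        fig.tight_layout()
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)


def save_roc_curves(fold_results, fig_path):
    """fold_results: list of (labels, scores) per fold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fig, ax = plt.subplots(figsize=(5, 4))
    for i, (y, s) in enumerate(fold_results):
        fpr, tpr, _ = roc_curve(y, s)
        ax.plot(fpr, tpr, lw=1, label=f"fold {i} (AUC {roc_auc(y, s):.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)
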