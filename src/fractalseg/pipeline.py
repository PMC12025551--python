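"""Training, evaluation, reporting and paired model comparison.

The training regimen mirrors the published setup: Adam at learning rate
0.001, batch size 8, binary cross-entropy on a sigmoid pixel output,
dropout 0.5 at the two deepest levels, 200 epochs at full scale (tests
and phantom smoke runs use far fewer).  Per-epoch training/validation
loss and pixel accuracy are recorded; the checkpoint with the best
validation loss is kept alongside the final state.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .data_io import SamplePair
from .metrics import BinaryMask, MetricReport, evaluate_pair
from .models import ArchitectureConfig, SegmentationModel, build_model
from .nn import Adam, bce_with_logits, no_grad

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "WilcoxonResult",
    "pairs_to_arrays",
    "train",
    "predict_proba",
    "predict_masks",
    "evaluate",
    "compare_models",
    "report",
    "save_checkpoint",
    "load_checkpoint",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("DSC", "VOE", "RVD", "ASD", "HD95", "REC", "PRE")


@dataclass(frozen=True)
class TrainConfig:
    """The published training regimen (defaults) plus run bookkeeping."""

    epochs: int = 200
    batch_size: int = 8
    learning_rate: float = 0.001
    dropout: float = 0.5
    optimizer: str = "adam"
    loss: str = "bce"
    output_activation: str = "sigmoid"
    seed: int = 0
    target: str = "csa"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs/batch_size must be >= 1 and learning_rate > 0")
        if self.target not in ("csa", "lesion"):
            raise ValueError("target must be 'csa' or 'lesion'")
        if self.optimizer != "adam" or self.loss != "bce":
            raise ValueError("supported regimen: Adam + binary cross-entropy")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_acc": self.train_acc,
                "val_acc": self.val_acc,
            }
        )


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_effective: int
    method: str
    all_zero: bool = False


def pairs_to_arrays(pairs: list[SamplePair], target: str = "csa"):
    """Stack pairs into (N,1,H,W) images and (N,1,H,W) {0,1} targets."""
    x = np.stack([p.image.pixels for p in pairs])[:, None].astype(np.float32)
    key = "csa_mask" if target == "csa" else "lesion_mask"
    y = np.stack([getattr(p, key).grid for p in pairs])[:, None].astype(np.float32)
    return x, y


def _epoch_metrics(model: SegmentationModel, x, y, batch_size: int):
    losses, accs, n = [], [], 0
    with no_grad():
        model.eval()
        for i in range(0, len(x), batch_size):
            xb, yb = x[i : i + batch_size], y[i : i + batch_size]
            logits = model.forward_logits(xb)
            losses.append(float(bce_with_logits(logits, yb).data) * len(xb))
            accs.append(float(((logits.data > 0) == (yb > 0.5)).mean()) * len(xb))
            n += len(xb)
        model.train()
    return sum(losses) / n, sum(accs) / n


def train(
    model: SegmentationModel,
    train_pairs: list[SamplePair],
    cfg: TrainConfig,
    val_pairs: list[SamplePair] | None = None,
    verbose: bool = False,
):
    """Optimize the model; returns (history, best_state, final_state).

    ``best_state`` is the parameter snapshot at the lowest validation
    loss (training loss when no validation pairs are given).
    """
    if not train_pairs:
        raise ValueError("empty training set")
    x, y = pairs_to_arrays(train_pairs, cfg.target)
    xv, yv = (pairs_to_arrays(val_pairs, cfg.target) if val_pairs else (None, None))

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    best = {"loss": np.inf, "state": model.state_dict()}

    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        ep_loss, ep_acc, n_seen = 0.0, 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            opt.zero_grad()
            logits = model.forward_logits(xb)
            loss = bce_with_logits(logits, yb)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}: {lv} "
                    "(check learning rate / input scaling)"
                )
            loss.backward(np.float32(1.0))
            opt.step()
            ep_loss += lv * len(idx)
            ep_acc += float(((logits.data > 0) == (yb > 0.5)).mean()) * len(idx)
            n_seen += len(idx)
        history.train_loss.append(ep_loss / n_seen)
        history.train_acc.append(ep_acc / n_seen)
        if xv is not None:
            vl, va = _epoch_metrics(model, xv, yv, cfg.batch_size)
        else:
            vl, va = history.train_loss[-1], history.train_acc[-1]
        history.val_loss.append(vl)
        history.val_acc.append(va)
        if vl < best["loss"]:
            best = {"loss": vl, "state": model.state_dict()}
        if verbose:
            print(
                f"epoch {epoch + 1:3d}/{cfg.epochs}  "
                f"loss {history.train_loss[-1]:.4f}  val_loss {vl:.4f}  val_acc {va:.4f}"
            )
    return history, best["state"], model.state_dict()


def predict_proba(model: SegmentationModel, pairs: list[SamplePair],
                  batch_size: int = 8) -> np.ndarray:
    """Per-pixel foreground probabilities, shape (N, H, W)."""
    x, _ = pairs_to_arrays(pairs, "csa")
    out = []
    with no_grad():
        model.eval()
        for i in range(0, len(x), batch_size):
            out.append(model.forward(x[i : i + batch_size]).data[:, 0])
        model.train()
    return np.concatenate(out)


def predict_masks(model: SegmentationModel, pairs: list[SamplePair],
                  threshold: float = 0.5, batch_size: int = 8) -> list[BinaryMask]:
    probs = predict_proba(model, pairs, batch_size=batch_size)
    return [
        BinaryMask((p >= threshold).astype(np.uint8), pair.image.spacing)
        for p, pair in zip(probs, pairs)
    ]


def evaluate(
    model: SegmentationModel,
    test_pairs: list[SamplePair],
    target: str = "csa",
    threshold: float = 0.5,
) -> tuple[dict, list[MetricReport], pd.DataFrame]:
    """Binarize predictions at ``threshold`` and score every test image.

    Returns the column means (one evaluation-table row), the per-image
    reports, and the per-image frame.  Means ignore undefined (NaN)
    entries, which only occur for degenerate ground truth.
    """
    preds = predict_masks(model, test_pairs, threshold=threshold)
    key = "csa_mask" if target == "csa" else "lesion_mask"
    reports = [evaluate_pair(pm, getattr(pair, key)) for pm, pair in zip(preds, test_pairs)]
    frame = pd.DataFrame([r.as_dict() for r in reports])
    frame.insert(0, "id", [p.identifier for p in test_pairs])
    row = {c: float(np.nanmean(frame[c].to_numpy(dtype=float))) for c in METRIC_COLUMNS}
    row["HD"] = float(np.nanmean(frame["HD"].to_numpy(dtype=float)))
    return row, reports, frame


def compare_models(per_image_a, per_image_b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-image scores.

    Zero differences are dropped (Wilcoxon's convention).  The exact
    null distribution (tie-aware) is used for n <= 25; beyond that the
    normal approximation with tie correction.  All-zero differences give
    p = 1 with a flag.
    """
    a = np.asarray(per_image_a, dtype=float)
    b = np.asarray(per_image_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score lists must be paired 1D arrays of equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_effective=0,
                              method="degenerate", all_zero=True)
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method=method, correction=False)
    return WilcoxonResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          n_effective=int(d.size), method=method)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: SegmentationModel) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> SegmentationModel:
    with np.load(Path(path), allow_pickle=False) as z:
        raw = {k: z[k] for k in z.files}
    cfg_dict = json.loads(bytes(raw.pop("__config__")).decode())
    cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
    cfg_dict["stage_widths"] = tuple(cfg_dict["stage_widths"])
    model = build_model(ArchitectureConfig(**cfg_dict), init=False)
    model.load_state_dict(raw)
    return model


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(
    tables: dict[str, dict],
    histories: dict[str, TrainHistory],
    out_dir,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write evaluation tables (CSV + Markdown), training curves
    (CSV + PNG) and run metadata (JSON).  Idempotent."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    table = pd.DataFrame.from_dict(tables, orient="index")
    table = table.reindex(columns=[c for c in (*METRIC_COLUMNS, "HD") if c in table.columns])
    table.index.name = "Architecture"
    written["table_csv"] = out / "evaluation.csv"
    table.to_csv(written["table_csv"], float_format="%.4f")
    written["table_md"] = out / "evaluation.md"
    written["table_md"].write_text(table.to_markdown(floatfmt=".2f") + "\n")

    if histories:
        curves = pd.concat(
            {name: h.as_frame().set_index("epoch") for name, h in histories.items()},
            names=["model"],
        )
        written["curves_csv"] = out / "curves.csv"
        curves.to_csv(written["curves_csv"])

        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
        panels = [("train_loss", "Training loss"), ("val_loss", "Validation loss"),
                  ("train_acc", "Training accuracy"), ("val_acc", "Validation accuracy")]
        for ax, (col, title) in zip(axes.ravel(), panels):
            for name, h in histories.items():
                ax.plot(h.as_frame()["epoch"], h.as_frame()[col], label=name)
            ax.set_title(title)
            ax.set_xlabel("epoch")
        axes[0, 0].legend(fontsize=8)
        fig.tight_layout()
        written["curves_png"] = out / "curves.png"
        fig.savefig(written["curves_png"], dpi=120)
        plt.close(fig)

    meta = dict(metadata or {})
    written["metadata"] = out / "metadata.json"
    written["metadata"].write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return written
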