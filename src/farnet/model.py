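"""Model/Results front end tying the pipeline together.

``FARNetModel`` is constructed from data (images + multi-hot targets, or
directly from a synthetic dataset spec), ``fit()`` runs the four-stage
training protocol and returns a ``FARNetResults`` carrying the trained
network, the loss curves, the held-out evaluation report and a ``summary()``
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneConfig
from .evaluation import EvalReport, confidence_grid, evaluate
from .relation import ARLParams, FARNet
from .synthdata import DatasetIndex, DatasetSpec, generate_dataset, split_dataset
from .training import StagePlan, TrainConfig, make_stage_plan, train

__all__ = ["FARNetModel", "FARNetResults"]


@dataclass
class FARNetModel:
    """A relation-network classifier bound to a dataset.

    Parameters
    ----------
    images : (N, H, W, 3) float array in [0, 1]
    y : (N, C) multi-hot targets
    label_names : C label identifiers, order fixing the channel order
    split : optional length-N array of 'train'/'val'/'test' tags; without it,
        ``fit`` trains on everything and evaluates in-sample
    """

    images: np.ndarray
    y: np.ndarray
    label_names: tuple[str, ...]
    split: np.ndarray | None = None
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    arl: ARLParams = field(default_factory=ARLParams)
    lfa_mid: int | None = None
    ablate: tuple[str, ...] = ()
    train_config: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int8)
        if len(self.images) != len(self.y):
            raise ValueError("images and targets disagree in length")
        unknown = set(self.ablate) - {"lfa", "ada", "arl"}
        if unknown:
            raise ValueError(f"unknown ablation flags: {sorted(unknown)}")

    @classmethod
    def from_spec(
        cls,
        spec: DatasetSpec,
        split_seed: int = 0,
        ratio=(3, 1, 1),
        **kwargs,
    ) -> "FARNetModel":
        """Generate the synthetic dataset described by ``spec`` (in memory),
        split it 3:1:1 stratified by label combination, and bind a model."""
        index, images = generate_dataset(spec)
        index = split_dataset(index, ratio=ratio, seed=split_seed)
        return cls.from_index(index, images, **kwargs)

    @classmethod
    def from_index(cls, index: DatasetIndex, images: dict[str, np.ndarray], **kwargs) -> "FARNetModel":
        stack = np.stack([images[i] for i in index.ids])
        split = (
            index.frame["split"].to_numpy() if "split" in index.frame.columns else None
        )
        return cls(
            images=stack,
            y=index.y,
            label_names=tuple(index.vocabulary.names),
            split=split,
            **kwargs,
        )

    def _mask(self, tag: str) -> np.ndarray:
        if self.split is None:
            return np.ones(len(self.y), dtype=bool)
        return self.split == tag

    def build_network(self, seed: int = 0) -> FARNet:
        return FARNet(
            self.backbone,
            n_labels=len(self.label_names),
            lfa_mid=self.lfa_mid,
            arl_params=self.arl,
            without_lfa="lfa" in self.ablate,
            without_ada="ada" in self.ablate,
            without_arl="arl" in self.ablate,
            seed=seed,
        )

    def fit(
        self,
        seed: int = 0,
        stages: tuple[int, ...] = (0, 1, 2, 3),
        plan: StagePlan | None = None,
        use_validation: bool = True,
        threshold: float = 0.5,
    ) -> "FARNetResults":
        """Train with the staged protocol and evaluate on the test split."""
        net = self.build_network(seed=seed)
        tr, va = self._mask("train"), self._mask("val")
        cfg = self.train_config
        if cfg.seed != seed:
            from dataclasses import replace

            cfg = replace(cfg, seed=seed)
        history = train(
            net,
            self.images[tr],
            self.y[tr],
            config=cfg,
            plan=plan or make_stage_plan(),
            val_images=self.images[va] if use_validation and self.split is not None else None,
            val_y=self.y[va] if use_validation and self.split is not None else None,
            stages=stages,
        )
        te = self._mask("test")
        conf = net.predict(self.images[te])
        report = evaluate(self.y[te], conf, self.label_names, threshold=threshold)
        return FARNetResults(
            model=self, network=net, history=history, report=report, test_confidences=conf
        )


@dataclass
class FARNetResults:
    model: FARNetModel
    network: FARNet
    history: dict
    report: EvalReport
    test_confidences: np.ndarray

    def predict(self, images) -> np.ndarray:
        return self.network.predict(images)

    def attention_weights(self, images=None) -> np.ndarray:
        """Mean relation-weight matrix over the test split (or given images)."""
        if images is None:
            images = self.model.images[self.model._mask("test")]
        return self.network.attention_weights(images)

    def confidence_grid(self, selected=("r", "mr", "c", "p"), figure_path=None) -> np.ndarray:
        return confidence_grid(
            self.test_confidences, self.model.label_names, selected, figure_path
        )

    def summary(self) -> str:
        lines = ["FAR-Net fit summary", "==================="]
        ablate = ", ".join(self.model.ablate) or "none"
        lines.append(f"backbone: {self.model.backbone.resolved().arch}   ablated: {ablate}")
        n_params = sum(p.data.size for p in self.network.parameters())
        lines.append(f"parameters: {n_params}")
        for rec in self.history["stages"]:
            if rec["loss"]:
                lines.append(
                    f"stage {rec['stage']} ({'+'.join(rec['trainable'])}): "
                    f"{len(rec['loss'])} iters, loss {rec['loss'][0]:.4f} → {rec['loss'][-1]:.4f}"
                )
        lines.append("")
        lines.append(self.report.to_table())
        return "\n".join(lines)
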