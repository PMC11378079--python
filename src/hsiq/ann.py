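"""Feed-forward inverse model: reflectance spectrum in, tissue parameters out.

The network maps a min-max-scaled 205-band diffuse reflectance spectrum to
the scaled 4-vector (log10 blood volume, oxygen saturation, melanin content,
scattering intensity) through three ReLU hidden layers, trained with Adam on
mean-squared error.  Training runs an explicit epoch loop over minibatches
so the validation split drives best-epoch selection and early stopping;
weights from the epoch with the lowest validation loss are restored.
Separate models are trained per tissue (skin, gingiva) since the anatomies
differ while the output vector is shared.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPRegressor

from .dataset import ScalerPair, SpectraCorpus
from .tissue import TissueParams

__all__ = ["NetworkConfig", "InverseModel", "train", "predict", "evaluate"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and optimization settings of the inverse network."""

    input_width: int = 205
    hidden: tuple = (256, 128, 64)
    output_width: int = 4
    activation: str = "relu"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 500
    patience: int = 25
    seed: int = 0

    def __post_init__(self):
        if len(self.hidden) != 3:
            raise ValueError("exactly three hidden layers")
        if any(w < 1 for w in self.hidden):
            raise ValueError("hidden widths must be >= 1")


@dataclass
class InverseModel:
    """Trained network plus the scalers needed to apply it."""

    mlp: MLPRegressor
    config: NetworkConfig
    scalers: ScalerPair
    wavelengths: np.ndarray
    history: list = field(default_factory=list)  # (epoch, train_mse, val_mse)

    # -- persistence -----------------------------------------------------

    def save(self, directory):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(
            d / "weights.npz",
            **{f"coef_{i}": c for i, c in enumerate(self.mlp.coefs_)},
            **{f"intercept_{i}": c for i, c in enumerate(self.mlp.intercepts_)},
            wavelengths=self.wavelengths,
        )
        (d / "config.json").write_text(json.dumps(asdict(self.config)))
        (d / "scalers.json").write_text(json.dumps(self.scalers.to_dict()))
        with open(d / "history.csv", "w") as fh:
            fh.write("epoch,train_mse,val_mse\n")
            for row in self.history:
                fh.write(",".join(f"{v:.8g}" for v in row) + "\n")

    @classmethod
    def load(cls, directory) -> "InverseModel":
        d = Path(directory)
        cfg_d = json.loads((d / "config.json").read_text())
        cfg_d["hidden"] = tuple(cfg_d["hidden"])
        config = NetworkConfig(**cfg_d)
        scalers = ScalerPair.from_dict(json.loads((d / "scalers.json").read_text()))
        with np.load(d / "weights.npz") as z:
            n_layers = len(config.hidden) + 1
            coefs = [z[f"coef_{i}"] for i in range(n_layers)]
            intercepts = [z[f"intercept_{i}"] for i in range(n_layers)]
            wavelengths = z["wavelengths"]
        mlp = _make_mlp(config)
        # initialize structures with a single dummy update, then overwrite
        x0 = np.zeros((2, config.input_width))
        y0 = np.zeros((2, config.output_width))
        mlp.partial_fit(x0, y0)
        mlp.coefs_ = coefs
        mlp.intercepts_ = intercepts
        history = []
        hist_path = d / "history.csv"
        if hist_path.exists():
            for line in hist_path.read_text().splitlines()[1:]:
                e, tr, va = line.split(",")
                history.append((int(float(e)), float(tr), float(va)))
        return cls(mlp, config, scalers, wavelengths, history)


def _make_mlp(config: NetworkConfig) -> MLPRegressor:
    return MLPRegressor(
        hidden_layer_sizes=tuple(config.hidden),
        activation=config.activation,
        solver=config.optimizer,
        learning_rate_init=config.learning_rate,
        batch_size=config.batch_size,
        random_state=config.seed,
        max_iter=1,
    )


def train(
    corpus: SpectraCorpus,
    scalers: ScalerPair,
    config: NetworkConfig | None = None,
) -> InverseModel:
    """Fit the inverse network on the training split of a corpus.

    Minimizes MSE on scaled targets; tracks validation MSE per epoch and
    restores the weights of the best validation epoch (early stopping after
    ``patience`` epochs without improvement).  Deterministic for a fixed
    config seed under single-threaded execution.
    """
    config = config or NetworkConfig(input_width=corpus.spectra.shape[1])
    if corpus.spectra.shape[1] != config.input_width:
        raise ValueError(
            f"corpus has {corpus.spectra.shape[1]} bands, "
            f"network expects {config.input_width}"
        )
    x_tr = scalers.transform_spectra(corpus.spectra[corpus.mask("train")])
    y_tr = scalers.transform_labels(corpus.labels[corpus.mask("train")])
    x_va = scalers.transform_spectra(corpus.spectra[corpus.mask("val")])
    y_va = scalers.transform_labels(corpus.labels[corpus.mask("val")])
    if x_tr.size == 0 or x_va.size == 0:
        raise ValueError("train and val splits must be non-empty")

    mlp = _make_mlp(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = x_tr.shape[0]
    best_val = np.inf
    best_state = None
    best_epoch = -1
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            mlp.partial_fit(x_tr[idx], y_tr[idx])
        tr_mse = float(np.mean((mlp.predict(x_tr) - y_tr) ** 2))
        va_mse = float(np.mean((mlp.predict(x_va) - y_va) ** 2))
        history.append((epoch, tr_mse, va_mse))
        if va_mse < best_val:
            best_val = va_mse
            best_epoch = epoch
            best_state = (
                copy.deepcopy(mlp.coefs_), copy.deepcopy(mlp.intercepts_)
            )
        elif epoch - best_epoch >= config.patience:
            break
    mlp.coefs_, mlp.intercepts_ = best_state
    return InverseModel(mlp, config, scalers, corpus.wavelengths.copy(), history)


def predict(model: InverseModel, spectra: np.ndarray):
    """Tissue-parameter estimates for raw (unscaled) reflectance spectra.

    Returns (B, S, fm, a) column arrays in original units; the blood channel
    is exponentiated back from its log10 representation.
    """
    spectra = np.atleast_2d(np.asarray(spectra, float))
    if spectra.shape[1] != model.config.input_width:
        raise ValueError("spectrum length does not match the model grid")
    y = model.scalers.inverse_labels(
        model.mlp.predict(model.scalers.transform_spectra(spectra))
    )
    return 10.0 ** y[:, 0], y[:, 1], y[:, 2], y[:, 3]


def evaluate(model: InverseModel, corpus: SpectraCorpus, split: str = "test",
             forward=None) -> dict:
    """Per-parameter RMSE (original units) and mean spectrum-fit RMSE.

    The spectrum-fit RMSE forward-models the predicted parameters (via the
    supplied lookup/engine) and takes the root-mean-square difference to the
    input spectrum, averaged over the split.
    """
    m = corpus.mask(split)
    if not m.any():
        raise ValueError(f"split {split!r} is empty")
    spectra = corpus.spectra[m]
    labels = corpus.labels[m]
    B, S, fm, a = predict(model, spectra)
    truth = corpus.params(split)
    report = {
        "rmse_B": float(np.sqrt(np.mean((B - truth.B) ** 2))),
        "rmse_S": float(np.sqrt(np.mean((S - truth.S) ** 2))),
        "rmse_fm": float(np.sqrt(np.mean((fm - truth.fm) ** 2))),
        "rmse_a": float(np.sqrt(np.mean((a - truth.a) ** 2))),
        "n": int(m.sum()),
    }
    if forward is not None:
        try:
            fitted = forward.spectra(B, S, fm, a, clip=True)
        except TypeError:
            fitted = forward.spectra(B, S, fm, a)
        per_spec = np.sqrt(np.mean((fitted - spectra) ** 2, axis=1))
        report["spectrum_rmse"] = float(per_spec.mean())
        report["spectrum_rmse_per_spectrum"] = per_spec
    return report
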