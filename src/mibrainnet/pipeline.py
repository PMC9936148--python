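"""End-to-end pipeline: preprocess -> mSCSP -> spectral/network features ->
fusion -> two-stage selection -> classifier ensemble.

Stateless per-trial stages (bandpass, denoising, wavelet energies) run once
over the whole EpochSet; every data-dependent stage (CSP filters and
channel choice, min-max scaling, mutcorLasso/relief-f selection, the
classifiers) is fitted on training trials only and re-fitted inside each
cross-validation fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassifierBundle, EvalReport, evaluate_features, predict_ensemble, train_classifiers
from .epochs import EpochSet, PipelineConfig
from .features import FeatureMatrix, MinMaxScaler
from .network import EnergyProfile, build_network, channel_energy_profiles, topology_features
from .preprocess import bandpass, wavelet_denoise
from .selection import SelectionResult, select_pipeline
from .spatial import CspModel, csp_trial_features, fit_mscsp

__all__ = ["Pipeline", "preprocess", "evaluate", "run_all"]


def preprocess(epochs: EpochSet, config: PipelineConfig) -> EpochSet:
    """Band-pass then wavelet-denoise; both are per-trial, so leakage-free."""
    out = bandpass(epochs, config.band_low, config.band_high)
    return wavelet_denoise(out, config.wavelet_name, config.denoise_level)


def _network_block(
    profiles: list[EnergyProfile],
    channel_idx: list[int],
    channel_names: list[str],
    sparsity: float,
) -> FeatureMatrix:
    """Entropy + topology features restricted to the selected channels."""
    idx = np.asarray(channel_idx, int)
    ch = [channel_names[i] for i in idx]
    rows = []
    for prof in profiles:
        sub = EnergyProfile(prof.E[idx], prof.P[idx], prof.S[idx], prof.components)
        topo = topology_features(build_network(sub, sparsity))
        rows.append(np.concatenate([
            sub.S, topo.degree, topo.clustering, topo.efficiency,
            [topo.norm1, topo.norm_spectral],
        ]))
    names = (
        [f"S_{c}" for c in ch] + [f"deg_{c}" for c in ch]
        + [f"clust_{c}" for c in ch] + [f"eff_{c}" for c in ch]
        + ["norm1", "norm_spectral"]
    )
    return FeatureMatrix(np.vstack(rows), names)


@dataclass
class Pipeline:
    """Fitted state of the data-dependent stages.

    ``fit`` expects already-preprocessed epochs (see :func:`preprocess`);
    ``transform`` maps compatible epochs to the final selected features.
    """

    config: PipelineConfig
    csp: CspModel | None = None
    scaler: MinMaxScaler | None = None
    selection: SelectionResult | None = None
    feature_names_: list[str] = field(default_factory=list)

    # -- feature extraction (stateless given the fitted CSP) -------------
    def _profiles(self, epochs: EpochSet) -> list[EnergyProfile]:
        cfg = self.config
        return [
            channel_energy_profiles(epochs.data[t], cfg.wavelet_name, cfg.decomposition_levels)
            for t in range(epochs.n_trials)
        ]

    def _fused(self, epochs: EpochSet, profiles: list[EnergyProfile] | None = None) -> FeatureMatrix:
        assert self.csp is not None, "pipeline not fitted"
        cfg = self.config
        profiles = profiles if profiles is not None else self._profiles(epochs)
        net = _network_block(
            profiles, self.csp.selected_channels, epochs.channel_names, cfg.sparsity
        )
        csp_fm = csp_trial_features(self.csp, epochs)
        return FeatureMatrix.hstack([net, csp_fm])

    # -- fit / transform --------------------------------------------------
    def fit(self, epochs: EpochSet, profiles: list[EnergyProfile] | None = None) -> "Pipeline":
        cfg = self.config
        self.csp = fit_mscsp(epochs, cfg.csp_filters_per_pair, cfg.n_channels_keep)
        fused = self._fused(epochs, profiles)
        self.scaler = MinMaxScaler().fit(fused)
        scaled = self.scaler.transform(fused)
        self.selection = select_pipeline(
            scaled, epochs.labels,
            n_keep_lasso=min(cfg.n_keep_lasso, scaled.n_features),
            n_keep_relief=min(cfg.n_keep_relief, scaled.n_features),
            alpha=cfg.alpha, beta=cfg.beta,
            relief_k=cfg.relief_k, relief_iters=cfg.relief_iters,
            relief_sample_rate=cfg.relief_sample_rate,
            bins=cfg.mi_bins, rng=np.random.default_rng(cfg.seed),
        )
        self.feature_names_ = self.selection.selected_names
        return self

    def transform(self, epochs: EpochSet, profiles: list[EnergyProfile] | None = None) -> FeatureMatrix:
        if self.selection is None or self.scaler is None:
            raise RuntimeError("pipeline not fitted")
        scaled = self.scaler.transform(self._fused(epochs, profiles))
        return scaled.subset(self.selection.selected)

    def fit_transform(self, epochs: EpochSet) -> FeatureMatrix:
        profiles = self._profiles(epochs)
        return self.fit(epochs, profiles).transform(epochs, profiles)


def evaluate(
    epochs: EpochSet,
    config: PipelineConfig,
    scheme: str = "kfold:10",
    repeats: int = 1,
    preprocessed: bool = False,
) -> EvalReport:
    """Cross-validated accuracy of the full pipeline (refit per fold)."""
    pp = epochs if preprocessed else preprocess(epochs, config)
    all_profiles = Pipeline(config)._profiles(pp)

    def fit_fn(tr: np.ndarray, te: np.ndarray):
        train = EpochSet(pp.data[tr], pp.labels[tr], pp.fs, list(pp.channel_names))
        test = EpochSet(pp.data[te], pp.labels[te], pp.fs, list(pp.channel_names))
        pipe = Pipeline(config).fit(train, [all_profiles[i] for i in tr])
        return (
            pipe.transform(train, [all_profiles[i] for i in tr]).values,
            pipe.transform(test, [all_profiles[i] for i in te]).values,
        )

    return evaluate_features(
        fit_fn, pp.labels, scheme=scheme, repeats=repeats,
        seed=config.seed, knn_k=config.knn_k, rf_trees=config.rf_trees,
    )


def run_all(
    epochs: EpochSet,
    config: PipelineConfig,
    out_dir: str | Path,
) -> tuple[FeatureMatrix, SelectionResult, np.ndarray]:
    """Fit the whole pipeline on ``epochs`` and persist its artifacts.

    Writes delimited text tables into ``out_dir``: the fused scaled feature
    matrix (``features.tsv``), both selection stages' weights
    (``selection.tsv``), the training-set predictions (``predictions.tsv``)
    and a plain-text summary. Byte-identical across runs at a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pp = preprocess(epochs, config)
    pipe = Pipeline(config)
    profiles = pipe._profiles(pp)
    pipe.fit(pp, profiles)
    assert pipe.scaler is not None and pipe.selection is not None
    fused_scaled = pipe.scaler.transform(pipe._fused(pp, profiles))
    selected = fused_scaled.subset(pipe.selection.selected)

    bundle = train_classifiers(
        selected.values, pp.labels, config.knn_k, config.rf_trees, config.seed
    )
    preds = bundle.predict_each(selected.values)
    preds["ensemble"] = predict_ensemble(bundle, selected.values)

    fused_scaled.to_tsv(out / "features.tsv")
    sel = pipe.selection
    stage2 = np.full(len(sel.names), np.nan)
    for local, global_i in enumerate(sel.lasso_selected):
        stage2[global_i] = sel.relief_weights[local]
    pd.DataFrame({
        "feature": sel.names,
        "stage1_w": sel.lasso_scores,
        "stage2_w": stage2,
        "kept": [int(i in set(sel.selected)) for i in range(len(sel.names))],
    }).to_csv(out / "selection.tsv", sep="\t", index=False, float_format="%.12g")
    pd.DataFrame({"label": pp.labels, **{k: v for k, v in preds.items()}}).to_csv(
        out / "predictions.tsv", sep="\t", index=False
    )
    (out / "summary.txt").write_text(
        "\n".join([
            *pp.provenance,
            f"selected features: {', '.join(sel.selected_names)}",
            f"training accuracy (ensemble): {float(np.mean(preds['ensemble'] == pp.labels)):.4f}",
        ]) + "\n"
    )
    return selected, sel, preds["ensemble"]
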