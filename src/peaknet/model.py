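"""Model/results facade over the accessibility CNN.

``AccessibilityCNN`` is constructed from data (encoded sequences plus a
binary site-by-cell activity matrix, or an HDF5 dataset container);
``fit`` trains the network and returns a :class:`FitResults` carrying
the learned parameters, the training history, evaluation utilities and
the downstream analyses (filter motifs, influence, saturation
mutagenesis, SAD scoring, transfer seeding).
"""

from __future__ import annotations

import numpy as np

from . import interpret, metrics, variants as variant_ops
from .datasets import load_checkpoint, load_dataset, save_checkpoint
from .nn import ArchitectureSpec, Network, default_architecture
from .peaks import DatasetSplit, split_dataset
from .sequence import encode_batch
from .train import TrainConfig, finetune_single_pass, train, transfer_seed


class AccessibilityCNN:
    """Multi-task CNN predicting per-cell accessibility from sequence.

    Parameters
    ----------
    sequences : (N, 4, L) one-hot array or list of equal-length strings
    activity : (N, T) binary matrix, one column per cell type
    arch : ArchitectureSpec, optional
        Defaults to the full three-conv-stage architecture for the data's
        sequence length.
    cell_names : list of str, optional
    split : DatasetSplit, optional
        Created from ``split_seed`` with the compendium-style default
        fractions (3.5% test, 3.4% validation) when omitted.
    """

    def __init__(self, sequences, activity, arch: ArchitectureSpec | None = None,
                 cell_names=None, split: DatasetSplit | None = None, split_seed=0):
        if isinstance(sequences, (list, tuple)):
            sequences = encode_batch(sequences)
        self.X = np.asarray(sequences)
        self.Y = np.asarray(activity)
        if self.X.ndim != 3 or self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("sequences and activity must align on sites")
        n, _, L = self.X.shape
        self.arch = arch or default_architecture(self.Y.shape[1], input_length=L)
        if self.arch.input_length != L:
            raise ValueError("architecture input_length disagrees with the data")
        if self.arch.n_targets != self.Y.shape[1]:
            raise ValueError("architecture n_targets disagrees with the data")
        self.cell_names = (list(cell_names) if cell_names is not None
                           else [f"cell_{t}" for t in range(self.Y.shape[1])])
        self.split = split or split_dataset(n, seed=split_seed)

    @classmethod
    def from_hdf5(cls, path, arch=None):
        """Build from a dataset container written by :func:`save_dataset`."""
        ds = load_dataset(path)
        return cls(ds.X, ds.Y, arch=arch, cell_names=ds.cell_names, split=ds.split)

    def fit(self, config: TrainConfig | None = None, dtype=np.float32,
            verbose=False) -> "FitResults":
        """Train with RMSprop + early stopping; returns the results object."""
        config = config or TrainConfig()
        network = Network(self.arch, seed=config.seed, dtype=dtype)
        history = train(network, self.X, self.Y, self.split.train_idx,
                        self.split.valid_idx, config, verbose=verbose)
        return FitResults(self, network, history, config)

    def results_from_checkpoint(self, path) -> "FitResults":
        network, _ = load_checkpoint(path)
        return FitResults(self, network, None, None)


class FitResults:
    """Fitted model: parameters, history, evaluation and analyses."""

    def __init__(self, model: AccessibilityCNN, network: Network, history, config):
        self.model = model
        self.network = network
        self.history = history
        self.config = config

    @property
    def params(self):
        return self.network.get_state()

    # -- prediction and evaluation ----------------------------------------

    def predict(self, X=None, idx=None):
        if X is None:
            X = self.model.X if idx is None else self.model.X[np.asarray(idx)]
        return self.network.predict(X)

    def evaluate(self, idx="test", keep_curves=False) -> metrics.EvalReport:
        """Accuracy on a split name ('train'/'valid'/'test') or index array."""
        if isinstance(idx, str):
            idx = getattr(self.model.split, f"{idx}_idx")
        idx = np.asarray(idx)
        preds = self.network.predict(self.model.X[idx])
        return metrics.evaluate(self.model.Y[idx], preds,
                                cell_names=self.model.cell_names,
                                keep_curves=keep_curves)

    def summary(self) -> str:
        """Human-readable fit summary with per-cell test accuracy."""
        rep = self.evaluate("test")
        spec = self.network.spec
        lines = [
            "Accessibility CNN fit",
            "=" * 54,
            f"sites: {len(self.model.X)}   targets: {spec.n_targets}   "
            f"input: {spec.input_length} bp",
            "conv stages: " + ", ".join(
                f"{nf}x{fw} (pool {pw})" for nf, fw, pw in spec.conv_layers),
            "fc stages:   " + ", ".join(str(u) for u in spec.fc_layers),
        ]
        if self.history is not None:
            lines += [
                f"epochs run: {self.history.n_epochs} "
                f"(best epoch {self.history.best_epoch}, "
                f"valid loss {min(self.history.valid_loss):.4f})",
            ]
        lines += ["-" * 54, f"{'cell':<24}{'AUC':>10}{'AUPRC':>10}"]
        for name, a, p in zip(rep.cell_names, rep.per_cell_auc, rep.per_cell_auprc):
            lines.append(f"{name:<24}{a:>10.4f}{p:>10.4f}")
        lines += ["-" * 54,
                  f"{'mean':<24}{rep.mean_auc:>10.4f}{rep.mean_auprc:>10.4f}"]
        return "\n".join(lines)

    # -- interpretation ----------------------------------------------------

    def _test_X(self, X=None):
        return self.model.X[self.model.split.test_idx] if X is None else np.asarray(X)

    def filter_pwms(self, X=None, **kwargs):
        """Half-max-counting PWMs of the first-layer filters (test set by default)."""
        return interpret.all_filter_pwms(self.network, self._test_X(X), **kwargs)

    def filter_influence(self, X=None, **kwargs):
        """Nullification influence profiles over the test set by default."""
        return interpret.filter_influence(self.network, self._test_X(X), **kwargs)

    def motif_insertion_effect(self, motif, X=None, **kwargs):
        return interpret.motif_insertion_effect(self.network, motif,
                                                self._test_X(X), **kwargs)

    # -- variant scoring ---------------------------------------------------

    def saturation_mutagenesis(self, seq, **kwargs) -> variant_ops.SatMutResult:
        return variant_ops.saturation_mutagenesis(self.network, seq, **kwargs)

    def sad_profile(self, genome, chrom, pos, ref, alt, snp_id="snp"):
        return variant_ops.sad_profile(self.network, genome, chrom, pos,
                                       ref, alt, snp_id)

    def score_vcf(self, genome, vcf_path):
        return variant_ops.score_vcf(self.network, genome, vcf_path)

    # -- transfer ----------------------------------------------------------

    def transfer(self, new_n_targets: int, seed: int = 0) -> Network:
        """Seed a new-model network from this fit (final layer re-initialized)."""
        return transfer_seed(self.network, new_n_targets, seed=seed)

    def finetune_transfer(self, X, Y, train_idx, config=None, seed=0) -> "FitResults":
        """Transfer-seed for ``Y.shape[1]`` targets and fine-tune with exactly
        one pass at half the learning rate."""
        Y = np.asarray(Y)
        net = self.transfer(Y.shape[1], seed=seed)
        finetune_single_pass(net, np.asarray(X), Y, train_idx, config)
        dummy = AccessibilityCNN.__new__(AccessibilityCNN)
        dummy.X, dummy.Y = np.asarray(X), Y
        dummy.arch = net.spec
        dummy.cell_names = [f"cell_{t}" for t in range(Y.shape[1])]
        dummy.split = None
        return FitResults(dummy, net, None, config)

    # -- persistence -------------------------------------------------------

    def save(self, path, meta=None):
        save_checkpoint(path, self.network, cell_names=self.model.cell_names,
                        meta=meta)
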