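"""End-to-end study orchestration.

Glues the simulator, preprocessing, both calibrations and the evaluation
stage into the two studies the package exists for: the calibration study
(database -> split -> CNN + ratio-regression control -> per-level metrics)
and the phantom study (tissue field -> droplet sampling -> pH map ->
resection mask vs ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import baseline as bl
from . import evaluation as ev
from . import mapping as mp
from . import network as nn
from .io import CHIP_GROUPS, SpectraDataset
from .preprocess import featurize_dataset
from .simulate import (ChipModel, PHField, ReporterModel, build_database,
                       synth_phantom)


def dataset_ratios(dataset: SpectraDataset) -> np.ndarray:
    """I527/I311 intensity ratio of every spectrum in the dataset."""
    return np.array([bl.intensity_ratio(s) for s in dataset.spectra])


def fit_ratio_calibration(
    ratios: np.ndarray, table: pd.DataFrame, train_mask: np.ndarray
) -> bl.RatioCalibration:
    """Per-chip lines plus the global logistic control, fit on the train split."""
    calib = bl.RatioCalibration()
    tr = np.asarray(train_mask)
    for chip_id, idx in table.groupby("chip_id").groups.items():
        sel = np.intersect1d(np.asarray(idx), np.flatnonzero(tr))
        calib.per_chip[chip_id] = bl.fit_chip_linear(
            ratios[sel], table["ph_tag"].to_numpy()[sel]
        )
    bl.fit_global_nonlinear(
        ratios[tr], table["ph_tag"].to_numpy()[tr], calib=calib
    )
    return calib


@dataclass
class CalibrationStudy:
    """Everything the calibration benchmark produces."""

    dataset: SpectraDataset
    chips: list[ChipModel]
    features: np.ndarray
    table: pd.DataFrame
    train_mask: np.ndarray
    model: nn.CNNCalibrator
    calib: bl.RatioCalibration
    cnn_ph: np.ndarray          # test-split predictions
    cnn_probs: np.ndarray
    reg_ph: np.ndarray
    metrics_cnn: ev.MetricsTable
    metrics_reg: ev.MetricsTable

    @property
    def test_table(self) -> pd.DataFrame:
        return self.table[~self.train_mask]

    def mae_in_range(self, lo: float = 6.0, hi: float = 7.5) -> float:
        """Test MAE restricted to nominal pH levels in [lo, hi]."""
        tags = self.test_table["ph_tag"].to_numpy()
        nominal = self.test_table["nominal_ph"].to_numpy()
        sel = (nominal >= lo - 1e-9) & (nominal <= hi + 1e-9)
        return float(np.mean(np.abs(self.cnn_ph[sel] - tags[sel])))

    def group_vote_accuracy(self) -> float:
        """Majority-vote chip-group accuracy over held-out spectra, per chip."""
        votes = np.argmax(self.cnn_probs, axis=1)
        test = self.test_table.reset_index(drop=True)
        correct = total = 0
        for chip_id, sub in test.groupby("chip_id"):
            counts = np.bincount(votes[sub.index.to_numpy()], minlength=len(CHIP_GROUPS))
            predicted = CHIP_GROUPS[int(np.argmax(counts))]
            correct += predicted == sub["chip_group"].iloc[0]
            total += 1
        return correct / total


def calibration_study(
    seed: int = 0,
    n_chips: int = 40,
    reps: int = 20,
    epochs: int | None = None,
    spec: nn.NetworkSpec | None = None,
    train_frac: float = 0.8,
) -> CalibrationStudy:
    """Run the full calibration benchmark on a freshly simulated database."""
    dataset, chips = build_database(n_chips=n_chips, reps=reps, seed=seed)
    nn.split_dataset(dataset, train_frac=train_frac, seed=seed)
    features, _, table = featurize_dataset(dataset)
    ratios = dataset_ratios(dataset)
    train_mask = (table["split"] == "train").to_numpy()

    model = nn.build_network(spec, seed=seed)
    nn.train(
        model,
        features[train_mask],
        table["ph_tag"].to_numpy()[train_mask],
        nn.encode_groups(table["chip_group"][train_mask]),
        seed=seed,
        epochs=epochs,
    )
    calib = fit_ratio_calibration(ratios, table, train_mask)

    test = ~train_mask
    cnn_ph, cnn_probs = model.predict(features[test])
    reg_ph = np.asarray(calib.predict_global(ratios[test]), dtype=float)
    tags = table["ph_tag"].to_numpy()[test]
    nominal = table["nominal_ph"].to_numpy()[test]
    metrics_cnn = ev.error_table(cnn_ph, tags, levels=nominal)
    metrics_reg = ev.error_table(reg_ph, tags, levels=nominal)
    return CalibrationStudy(
        dataset=dataset, chips=chips, features=features, table=table,
        train_mask=train_mask, model=model, calib=calib,
        cnn_ph=cnn_ph, cnn_probs=cnn_probs, reg_ph=reg_ph,
        metrics_cnn=metrics_cnn, metrics_reg=metrics_reg,
    )


@dataclass
class PhantomStudy:
    field: PHField
    chip: ChipModel
    ph_map: mp.PHMap
    mask: mp.ResectionMask
    dice: float
    abs_error: np.ndarray

    def fraction_within(self, tol: float = 0.25) -> float:
        return float(np.mean(self.abs_error <= tol))


def phantom_study(
    model,
    chip: ChipModel,
    seed: int = 0,
    rows: int = 8,
    cols: int = 8,
    reporter: ReporterModel | None = None,
    field: PHField | None = None,
) -> PhantomStudy:
    """Map a simulated tumor bed with a trained model and score the recovery."""
    if field is None:
        field = synth_phantom(rows=rows, cols=cols, seed=seed)
    measurements = mp.sample_phantom(field, chip, model, seed=seed, reporter=reporter)
    ph_map = mp.assemble_map(
        measurements, *field.ph.shape, pixel_mm=field.pixel_mm, chip_id=chip.chip_id
    )
    mask = mp.resection_mask(ph_map)
    dice = mp.dice_coefficient(mask.mask, field.tumor_mask)
    abs_error = np.abs(ph_map.values - field.ph)
    return PhantomStudy(
        field=field, chip=chip, ph_map=ph_map, mask=mask,
        dice=dice, abs_error=abs_error,
    )
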