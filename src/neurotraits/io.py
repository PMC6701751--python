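"""Readers and writers for the pipeline's delimited-text interfaces.

Everything on disk is plain TSV/JSON so cohorts, models and results can
be inspected and versioned: subscales.tsv, traits.tsv, loadings.tsv,
nodes.tsv, pain.tsv, demographics.tsv, per-scan connectivity TSVs, a
truth.json with the generator's ground truth, and neurotrait model JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .connectome import NeurotraitModel
from .simulate import SyntheticCohort


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_cohort(cohort: SyntheticCohort, out_dir, connectivity: bool = True) -> None:
    """Write a synthetic cohort to a directory of TSVs plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(cohort.subscales, out / "subscales.tsv")
    write_tsv(cohort.pain_measures, out / "pain.tsv")
    write_tsv(cohort.demographics, out / "demographics.tsv")
    write_tsv(cohort.nodes, out / "nodes.tsv")
    pd.DataFrame({"mean_fd": cohort.motion}).to_csv(
        out / "motion.tsv", sep="\t", index=False
    )
    if connectivity:
        conn_dir = out / "connectivity"
        conn_dir.mkdir(exist_ok=True)
        cfg = cohort.config
        for i in range(cfg.n_subjects):
            for s in range(cfg.n_sessions):
                M = cohort.connectivity.matrix(i, s)
                np.savetxt(conn_dir / f"connectivity_{i:03d}_V{s + 2}.tsv",
                           M, delimiter="\t", fmt="%.6f")
    truth = {
        "config": {k: v for k, v in vars(cohort.config).items()},
        "loadings": cohort.true_loadings.tolist(),
        "factor_scores": cohort.true_factor_scores.tolist(),
        "planted_positive": {str(k): v.tolist()
                             for k, v in cohort.planted_edges.positive.items()},
        "planted_negative": {str(k): v.tolist()
                             for k, v in cohort.planted_edges.negative.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


def write_model(model: NeurotraitModel, path) -> None:
    payload = {
        "trait": model.trait,
        "sign": model.sign,
        "n_nodes": model.n_nodes,
        "weights": {str(k): v for k, v in model.weights.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path) -> NeurotraitModel:
    payload = json.loads(Path(path).read_text())
    return NeurotraitModel(
        trait=payload["trait"],
        sign=payload["sign"],
        n_nodes=payload["n_nodes"],
        weights={int(k): float(v) for k, v in payload["weights"].items()},
    )


def read_connectivity_dir(conn_dir, session: Optional[str] = None) -> np.ndarray:
    """Load per-scan P x P TSVs into an (n_subjects, E) edge array.

    Files follow ``connectivity_{subject}_{session}.tsv``; subjects are
    ordered by filename.  If ``session`` is given only matching scans
    are loaded.
    """
    conn_dir = Path(conn_dir)
    files = sorted(conn_dir.glob("connectivity_*.tsv"))
    if session is not None:
        files = [f for f in files if f.stem.endswith(session)]
    if not files:
        raise FileNotFoundError(f"no connectivity TSVs in {conn_dir}")
    rows = []
    for f in files:
        M = np.loadtxt(f, delimiter="\t")
        iu, ju = np.triu_indices(M.shape[0], 1)
        rows.append(M[iu, ju])
    return np.vstack(rows)
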