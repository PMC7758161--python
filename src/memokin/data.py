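"""Study containers and CSV input for the labeling + telomere analysis.

One :class:`VolunteerDataset` bundles everything the joint fit needs for a
single volunteer-lineage: the saliva enrichment series (to parameterise
the body-water curve), the per-subset DNA label enrichment series, the
per-subset telomere observations and, optionally, the measured
CD57-/CD57+ pool-size ratio R.

CSV schemas
-----------
saliva.csv    : volunteer_id, day, enrichment
labels.csv    : volunteer_id, lineage, subset, day, enrichment
telomeres.csv : volunteer_id, lineage, subset, molecule_id,
                telomere_length_bp   (per-molecule STELA records)
                -- or --
                volunteer_id, lineage, subset, mean_length_bp
ratios.csv    : volunteer_id, lineage, R          (optional)

``subset`` is "CD57neg" or "CD57pos"; ``lineage`` is "CD4" or "CD8";
enrichments are dimensionless fractions; days count from the start of
labeling.  Validation failures are collected with line numbers and raised
together as a :class:`~memokin.exceptions.SchemaError`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bodywater import SalivaSeries
from .exceptions import SchemaError
from .telomere import TelomereObservation, observed_mean_difference

__all__ = ["LabelSeries", "VolunteerDataset", "read_study", "write_study"]

SUBSETS = ("CD57neg", "CD57pos")
LINEAGES = ("CD4", "CD8")


@dataclass(frozen=True)
class LabelSeries:
    """DNA label enrichment observations for one subset."""

    subset: str
    days: np.ndarray
    enrichment: np.ndarray

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        enr = np.asarray(self.enrichment, dtype=float)
        if days.ndim != 1 or days.shape != enr.shape:
            raise SchemaError("label days/enrichment must be 1-D, equal length")
        order = np.argsort(days)
        object.__setattr__(self, "days", days[order])
        object.__setattr__(self, "enrichment", enr[order])

    def __len__(self):
        return len(self.days)


@dataclass
class VolunteerDataset:
    """All measurements for one volunteer-lineage."""

    volunteer_id: str
    lineage: str
    saliva: SalivaSeries | None
    labels: dict[str, LabelSeries]
    telomeres: dict[str, TelomereObservation] | None = None
    R: float | None = None

    def __post_init__(self):
        if set(self.labels) != set(SUBSETS):
            raise SchemaError(
                f"label subsets must be exactly {set(SUBSETS)}, got {set(self.labels)}"
            )
        if self.telomeres is not None and set(self.telomeres) != set(SUBSETS):
            raise SchemaError("telomere subsets must be exactly CD57neg/CD57pos")

    @property
    def key(self) -> tuple[str, str]:
        return (self.volunteer_id, self.lineage)

    @property
    def has_telomere(self) -> bool:
        return self.telomeres is not None

    @property
    def n_label_obs(self) -> int:
        return sum(len(s) for s in self.labels.values())

    def delta_obs(self) -> float:
        """Observed telomere-length difference, CD57- minus CD57+ (bp)."""
        if not self.has_telomere:
            raise SchemaError(f"{self.key}: no telomere data")
        return observed_mean_difference(
            self.telomeres["CD57neg"], self.telomeres["CD57pos"]
        )


def _require_columns(df: pd.DataFrame, cols: set[str], name: str):
    missing = cols - set(df.columns)
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {sorted(missing)}")


def _row_errors(df: pd.DataFrame, name: str, checks) -> list[str]:
    """Apply (predicate, message) pairs row-wise; line numbers are 1-based
    file lines (header = line 1)."""
    errors = []
    for pred, msg in checks:
        bad = df.index[pred(df)]
        errors.extend(f"{name} line {i + 2}: {msg}" for i in bad)
    return errors


def read_study(
    saliva_csv,
    labels_csv,
    telomere_csv=None,
    ratios_csv=None,
) -> list[VolunteerDataset]:
    """Read and validate a study from CSV files.

    Returns one dataset per (volunteer_id, lineage) appearing in the label
    table, sorted by volunteer then lineage.  Telomere and ratio data are
    attached where available; datasets without telomere data are still
    returned (they get a label-only fit downstream).
    """
    errors: list[str] = []

    saliva = pd.read_csv(saliva_csv)
    _require_columns(saliva, {"volunteer_id", "day", "enrichment"}, "saliva")
    errors += _row_errors(saliva, "saliva", [
        (lambda d: d["enrichment"] < 0, "negative enrichment"),
        (lambda d: d["day"] < 0, "negative day"),
    ])
    dup = saliva.duplicated(subset=["volunteer_id", "day"])
    errors += [f"saliva line {i + 2}: duplicate (volunteer, day)"
               for i in saliva.index[dup]]

    labels = pd.read_csv(labels_csv)
    _require_columns(
        labels, {"volunteer_id", "lineage", "subset", "day", "enrichment"}, "labels"
    )
    errors += _row_errors(labels, "labels", [
        (lambda d: d["enrichment"] < 0, "negative enrichment"),
        (lambda d: d["day"] < 0, "negative day"),
        (lambda d: ~d["subset"].isin(SUBSETS), "unknown subset"),
        (lambda d: ~d["lineage"].isin(LINEAGES), "unknown lineage"),
    ])
    dup = labels.duplicated(subset=["volunteer_id", "lineage", "subset", "day"])
    errors += [f"labels line {i + 2}: duplicate (volunteer, lineage, subset, day)"
               for i in labels.index[dup]]

    telo = None
    if telomere_csv is not None:
        telo = pd.read_csv(telomere_csv)
        _require_columns(telo, {"volunteer_id", "lineage", "subset"}, "telomeres")
        if "telomere_length_bp" in telo.columns:
            errors += _row_errors(telo, "telomeres", [
                (lambda d: d["telomere_length_bp"] <= 0, "nonpositive length"),
            ])
        elif "mean_length_bp" in telo.columns:
            errors += _row_errors(telo, "telomeres", [
                (lambda d: d["mean_length_bp"] <= 0, "nonpositive mean length"),
            ])
        else:
            raise SchemaError(
                "telomeres: need either telomere_length_bp or mean_length_bp"
            )

    ratios = None
    if ratios_csv is not None:
        ratios = pd.read_csv(ratios_csv)
        _require_columns(ratios, {"volunteer_id", "lineage", "R"}, "ratios")
        errors += _row_errors(ratios, "ratios", [
            (lambda d: d["R"] <= 0, "nonpositive ratio"),
        ])

    if errors:
        raise SchemaError("study input validation failed", errors)

    datasets = []
    for (vid, lineage), sub in sorted(labels.groupby(["volunteer_id", "lineage"])):
        label_series = {}
        for subset in SUBSETS:
            ss = sub[sub["subset"] == subset]
            if ss.empty:
                raise SchemaError(f"({vid}, {lineage}): no {subset} label data")
            label_series[subset] = LabelSeries(
                subset, ss["day"].to_numpy(float), ss["enrichment"].to_numpy(float)
            )

        sal = None
        if (saliva["volunteer_id"] == vid).any():
            sal = SalivaSeries.from_dataframe(saliva, vid)

        telomeres = None
        if telo is not None:
            tt = telo[(telo["volunteer_id"] == vid) & (telo["lineage"] == lineage)]
            if not tt.empty and set(tt["subset"]) == set(SUBSETS):
                telomeres = {}
                for subset in SUBSETS:
                    ts = tt[tt["subset"] == subset]
                    if "telomere_length_bp" in ts.columns and ts[
                        "telomere_length_bp"
                    ].notna().any():
                        telomeres[subset] = TelomereObservation(
                            subset, lengths=ts["telomere_length_bp"].to_numpy(float)
                        )
                    else:
                        telomeres[subset] = TelomereObservation(
                            subset, mean_bp=float(ts["mean_length_bp"].iloc[0])
                        )

        r_val = None
        if ratios is not None:
            rr = ratios[
                (ratios["volunteer_id"] == vid) & (ratios["lineage"] == lineage)
            ]
            if not rr.empty:
                r_val = float(rr["R"].iloc[0])

        datasets.append(
            VolunteerDataset(
                volunteer_id=str(vid), lineage=str(lineage), saliva=sal,
                labels=label_series, telomeres=telomeres, R=r_val,
            )
        )
    return datasets


def write_study(datasets: list[VolunteerDataset], outdir) -> dict:
    """Write a study back to the four CSV schemas; returns the paths.

    Saliva rows are deduplicated across lineages of the same volunteer
    (the saliva series is a per-volunteer measurement).
    """
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sal_rows, label_rows, telo_rows, ratio_rows = [], [], [], []
    saliva_seen = set()
    for ds in datasets:
        if ds.saliva is not None and ds.volunteer_id not in saliva_seen:
            saliva_seen.add(ds.volunteer_id)
            for d, e in zip(ds.saliva.days, ds.saliva.enrichment):
                sal_rows.append(
                    {"volunteer_id": ds.volunteer_id, "day": d, "enrichment": e}
                )
        for subset, series in ds.labels.items():
            for d, e in zip(series.days, series.enrichment):
                label_rows.append({
                    "volunteer_id": ds.volunteer_id, "lineage": ds.lineage,
                    "subset": subset, "day": d, "enrichment": e,
                })
        if ds.telomeres is not None:
            for subset, obs in ds.telomeres.items():
                if obs.lengths is not None:
                    for i, length in enumerate(obs.lengths):
                        telo_rows.append({
                            "volunteer_id": ds.volunteer_id,
                            "lineage": ds.lineage, "subset": subset,
                            "molecule_id": i, "telomere_length_bp": length,
                        })
                else:
                    telo_rows.append({
                        "volunteer_id": ds.volunteer_id, "lineage": ds.lineage,
                        "subset": subset, "molecule_id": 0,
                        "telomere_length_bp": obs.mean_bp,
                    })
        if ds.R is not None:
            ratio_rows.append({
                "volunteer_id": ds.volunteer_id, "lineage": ds.lineage,
                "R": ds.R,
            })

    paths = {}
    for name, rows in (
        ("saliva", sal_rows), ("labels", label_rows),
        ("telomeres", telo_rows), ("ratios", ratio_rows),
    ):
        if not rows and name in ("telomeres", "ratios"):
            continue
        path = outdir / f"{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        paths[name] = path
    return paths
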