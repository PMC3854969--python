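"""Table and configuration I/O.

All tables are tab-separated (symbols and protein names contain commas);
the 'nd' token marks TAP proteins not detected by SILAC.  Counts and
enrichment factors are written with one decimal, mirroring the summary
complex table; fit parameters are written at full precision.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .apms import ND, ComplexTableRow, SilacProteinRecord, TapProteinRecord
from .frap import RecoveryFit
from .kymo import Track
from .simulate import IFTParams, IntensityTrace, NoiseParams, SimConfig

__all__ = [
    "load_complex_table",
    "write_complex_table",
    "packaged_table1",
    "write_trace",
    "read_trace",
    "write_fits",
    "write_tracks",
    "read_tap_records",
    "read_silac_records",
    "load_sim_config",
]

COMPLEX_COLUMNS = ["symbol", "name", "tap_count", "silac_enrichment"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def load_complex_table(path: str | Path) -> list[ComplexTableRow]:
    """Read a summary complex table (TSV) into typed rows."""
    df = _read_tsv(path, COMPLEX_COLUMNS)
    rows: list[ComplexTableRow] = []
    for i, rec in df.iterrows():
        token = rec["silac_enrichment"].strip()
        try:
            enrichment: float | str = ND if token == ND else float(token)
            count = float(rec["tap_count"])
        except ValueError as exc:
            raise ValueError(f"row {i + 2}: unparseable cell ({exc})") from None
        rows.append(
            ComplexTableRow(
                symbol=rec["symbol"],
                name=rec["name"],
                avg_tap_count=count,
                silac_enrichment=enrichment,
            )
        )
    return rows


def write_complex_table(rows: list[ComplexTableRow], path: str | Path) -> None:
    """Write a summary complex table; counts to one decimal, 'nd' preserved."""
    with open(path, "w") as fh:
        fh.write("\t".join(COMPLEX_COLUMNS) + "\n")
        for r in rows:
            silac = r.silac_enrichment if isinstance(r.silac_enrichment, str) \
                else f"{r.silac_enrichment:.1f}"
            fh.write(f"{r.symbol}\t{r.name}\t{r.avg_tap_count:.1f}\t{silac}\n")


def packaged_table1() -> list[ComplexTableRow]:
    """The packaged transcription of the published ARL13B complex table."""
    ref = importlib.resources.files("ciliagate.data") / "table1_arl13b_complex.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_complex_table(path)


# --------------------------------------------------------------------------
# traces, fits, tracks
# --------------------------------------------------------------------------

def write_trace(trace: IntensityTrace, path: str | Path) -> None:
    """Trace TSV: time_s, one column per ROI, background."""
    df = pd.DataFrame(trace.raw, columns=trace.roi_names)
    df.insert(0, "time_s", trace.times)
    df["background"] = trace.background
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_trace(path: str | Path) -> IntensityTrace:
    df = _read_tsv(path, ["time_s", "background"])
    roi_names = [c for c in df.columns if c not in ("time_s", "background")]
    if not roi_names:
        raise ValueError(f"{path}: no ROI columns")
    return IntensityTrace(
        times=df["time_s"].astype(float).to_numpy(),
        roi_names=roi_names,
        raw=df[roi_names].astype(float).to_numpy(),
        background=float(df["background"].astype(float).iloc[0]),
    )


def write_fits(fits: dict[str, RecoveryFit], path: str | Path) -> None:
    """Recovery fits as TSV with stable full-precision formatting."""
    with open(path, "w") as fh:
        fh.write(
            "label\tk_per_s\tt_half_s\tf0\tplateau\tr_squared\tn_points"
            "\tconverged\tpasses_gate\n"
        )
        for label, f in fits.items():
            fh.write(
                f"{label}\t{f.k:.10g}\t{f.t_half:.10g}\t{f.f0:.10g}"
                f"\t{f.plateau:.10g}\t{f.r_squared:.10g}\t{f.n_points}"
                f"\t{f.converged}\t{f.passes_gate}\n"
            )


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    """Tracks TSV: track_id, frame, position_px, velocity_um_s."""
    with open(path, "w") as fh:
        fh.write("track_id\tframe\tposition_px\tvelocity_um_s\n")
        for i, tr in enumerate(tracks):
            for f, p in tr.points:
                fh.write(f"{i}\t{f}\t{p:.6g}\t{tr.velocity:.6g}\n")


# --------------------------------------------------------------------------
# AP-MS record tables
# --------------------------------------------------------------------------

def read_tap_records(path: str | Path) -> list[TapProteinRecord]:
    """TAP records TSV: symbol, count_1..count_N, peptide_probability,
    protein_probability, control_frequency, is_bait[, name]."""
    df = _read_tsv(
        path,
        ["symbol", "peptide_probability", "protein_probability",
         "control_frequency", "is_bait"],
    )
    count_cols = sorted(
        (c for c in df.columns if c.startswith("count_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not count_cols:
        raise ValueError(f"{path}: no count_<i> columns")
    records = []
    for i, rec in df.iterrows():
        try:
            records.append(
                TapProteinRecord(
                    symbol=rec["symbol"],
                    counts=tuple(int(rec[c]) for c in count_cols),
                    peptide_probability=float(rec["peptide_probability"]),
                    protein_probability=float(rec["protein_probability"]),
                    control_frequency=float(rec["control_frequency"]),
                    is_bait=rec["is_bait"].strip().lower() in ("true", "1", "yes"),
                    name=rec.get("name", ""),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {i + 2}: {exc}") from None
    return records


def read_silac_records(path: str | Path) -> list[SilacProteinRecord]:
    """SILAC records TSV: symbol, log2_ratio_1..N, peptides_1..N."""
    df = _read_tsv(path, ["symbol"])
    ratio_cols = sorted(
        (c for c in df.columns if c.startswith("log2_ratio_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    pep_cols = sorted(
        (c for c in df.columns if c.startswith("peptides_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if not ratio_cols or len(ratio_cols) != len(pep_cols):
        raise ValueError(f"{path}: need matching log2_ratio_<i>/peptides_<i> columns")
    records = []
    for i, rec in df.iterrows():
        try:
            records.append(
                SilacProteinRecord(
                    symbol=rec["symbol"],
                    log2_ratios=tuple(float(rec[c]) for c in ratio_cols),
                    peptides_quantified=tuple(int(rec[c]) for c in pep_cols),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {i + 2}: {exc}") from None
    return records


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def load_sim_config(path: str | Path) -> SimConfig:
    """Load a simulator configuration from YAML (units: µm, s, au)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
    if "ift" in raw and raw["ift"] is not None:
        raw["ift"] = IFTParams(**raw["ift"])
    if "noise" in raw and raw["noise"] is not None:
        raw["noise"] = NoiseParams(**raw["noise"])
    cfg = SimConfig(**raw)
    cfg.validate()
    return cfg
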