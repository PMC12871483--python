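"""Readers and writers: NSE TSV dialect, config files, fit reports.

File-boundary units follow NSE community convention (q in 1/A, Fourier
time in ns); everything in memory is SI.  Tables are plain TSV with
'#'-prefixed ``key: value`` metadata header lines and the column header
``q_invA  t_ns  sqt  sqt_err``.
"""

from __future__ import annotations

import configparser
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import RelaxationDataset
from .errors import ParseError
from .fitting import FitResult, PerQFitResult

__all__ = ["read_nse_table", "write_nse_table", "write_fit_report",
           "read_config"]

INV_ANGSTROM = 1e10
NS = 1e-9

_HEADER = ("q_invA", "t_ns", "sqt", "sqt_err")


def write_nse_table(dataset: RelaxationDataset, path) -> None:
    """Write a dataset in the NSE TSV dialect (round-trips to 1e-12)."""
    path = Path(path)
    lines = []
    for key, val in dataset.metadata.items():
        lines.append(f"# {key}: {val}")
    lines.append("\t".join(_HEADER))
    for row in dataset.table.itertuples(index=False):
        lines.append("\t".join([
            f"{row.q / INV_ANGSTROM:.17g}", f"{row.t / NS:.17g}",
            f"{row.s:.17g}", f"{row.err:.17g}"]))
    path.write_text("\n".join(lines) + "\n")


def read_nse_table(path) -> RelaxationDataset:
    """Parse an NSE TSV file; malformed rows raise :class:`ParseError`
    naming the line.  The uncertainty column is mandatory."""
    path = Path(path)
    meta: dict = {}
    rows = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip()
                if key in meta:
                    raise ParseError(f"duplicate metadata key {key!r}", lineno)
                meta[key] = _coerce(val.strip())
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(fields) != _HEADER:
                if len(fields) < 4:
                    raise ParseError(
                        "missing columns: the uncertainty column is "
                        "mandatory", lineno)
                raise ParseError(
                    f"expected header {_HEADER}, found {tuple(fields)}", lineno)
            header_seen = True
            continue
        if len(fields) != 4:
            raise ParseError(f"expected 4 columns, found {len(fields)}", lineno)
        try:
            q, t, s, err = (float(f) for f in fields)
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
        if not np.isfinite([q, t, s, err]).all():
            raise ParseError("non-finite value", lineno)
        if err <= 0:
            raise ParseError(f"non-positive uncertainty {err:g}", lineno)
        rows.append((q * INV_ANGSTROM, t * NS, s, err))
    if not header_seen:
        raise ParseError("no column header found", None)
    df = pd.DataFrame(rows, columns=["q", "t", "s", "err"])
    return RelaxationDataset(df, meta)


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


# ----------------------------------------------------------------------
def read_config(path) -> dict:
    """Read a flat ``key = value`` config with ``[sections]`` into a
    nested dict of coerced values (e.g. ``cfg['diffusion']['mode']``)."""
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    return {section: {k: _coerce(v) for k, v in parser.items(section)}
            for section in parser.sections()}


# ----------------------------------------------------------------------
def _dataset_hash(dataset: RelaxationDataset | None) -> str | None:
    if dataset is None:
        return None
    payload = dataset.table.to_csv(index=False, float_format="%.17g")
    return hashlib.sha256(payload.encode()).hexdigest()


def write_fit_report(result, path_prefix, dataset: RelaxationDataset | None = None):
    """Write ``<prefix>.tsv`` (per-q table, if any) and ``<prefix>.json``.

    The JSON summary always records the tension and membrane viscosity,
    fitted or fixed, plus the software version and an input hash.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    summary = {
        "software": f"vesiclense {__version__}",
        "input_sha256": _dataset_hash(dataset),
    }
    if isinstance(result, PerQFitResult):
        frame = result.frame
        summary.update({
            "mode": "per_q",
            "temperature_K": result.temperature,
            "fixed": result.fixed,
            "sigma_N_per_m": result.fixed.get("sigma_N_per_m"),
            "eta_m_Pa_s_m": result.fixed.get("eta_m_Pa_s_m"),
            "kappa_kT_per_q": frame["kappa_kT"].tolist(),
        })
    elif isinstance(result, FitResult):
        frame = None
        kT = result.params.get("kappa_tilde")
        summary.update({
            "mode": "global",
            "temperature_K": result.temperature,
            "parameters_SI": result.params,
            "kappa_tilde_kT": (result.kappa_tilde_kT
                               if "kappa_tilde" in result.params else None),
            "uncertainties_SI": result.bse,
            "fixed": result.fixed,
            "sigma_N_per_m": result.params.get(
                "sigma", result.fixed.get("sigma_N_per_m")),
            "eta_m_Pa_s_m": result.params.get(
                "eta_m", result.fixed.get("eta_m_Pa_s_m")),
            "chi2_reduced": result.redchi,
            "flags": list(result.flags),
            "messages": list(result.messages),
        })
        _ = kT
    else:
        raise TypeError(f"cannot report {type(result).__name__}")

    if frame is not None:
        tsv_path = prefix.with_suffix(".tsv")
        frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(summary, indent=2, default=float) + "\n")
    return json_path
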