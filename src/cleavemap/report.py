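"""Visual and bundled reporting: heatmaps, percent-difference logos, and a
checksummed run-report directory.

The percent-difference logo shows, per subsite, the observed residue
frequency minus a reference composition, in percentage points, with
non-significant cells masked.  Significance is a two-sided exact binomial
test of the observed count against the reference frequency at the
subsite's defined-observation count; no multiple-testing correction is
applied, and the mask threshold is the conventional p < 0.05.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
matplotlib.use("Agg")  # noqa: E402 — headless rendering
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats as sps

from ._aa import AMINO_ACIDS
from .motifs import PairMatrix
from .profile import BackgroundComposition, SpecificityMatrix
from .stats import LengthSummary, MissedCleavageReport

logger = logging.getLogger(__name__)

__all__ = [
    "LogoMatrix",
    "percent_difference_logo",
    "render_heatmap",
    "render_logo",
    "run_report",
]

# Fixed salt makes matplotlib's SVG element ids reproducible run to run.
matplotlib.rcParams["svg.hashsalt"] = "cleavemap"


@dataclass
class LogoMatrix:
    """Percent-difference logo content: per-cell differences (percentage
    points), two-sided binomial p-values, and the significance mask."""

    diff: np.ndarray     # 20 x S, observed - reference, percentage points
    pvals: np.ndarray    # 20 x S
    masked: np.ndarray   # 20 x S bool; True = not significant, hidden
    subsites: list[str]
    alpha: float = 0.05


def percent_difference_logo(
    matrix: SpecificityMatrix,
    reference: BackgroundComposition,
    alpha: float = 0.05,
) -> LogoMatrix:
    """Build the percent-difference logo matrix.

    ``diff[r][s] = 100 * (f_obs[r][s] - q[r])`` with q the reference
    residue frequency; each subsite's differences sum to zero because both
    frequency vectors sum to one.  Cells with p >= alpha are masked;
    ``alpha >= 1`` is the degenerate threshold that masks nothing.
    """
    q = reference.residue_vector()
    f = matrix.frequencies
    diff = 100.0 * (f - q[:, None])
    pvals = np.ones_like(diff)
    for s, n in enumerate(matrix.n_defined):
        if n < 1:
            continue
        for r in range(len(AMINO_ACIDS)):
            qr = q[r]
            k = int(matrix.counts[r, s])
            if qr <= 0.0 or qr >= 1.0:
                # degenerate reference: the observation either matches the
                # certain outcome (p = 1) or contradicts it (p = 0)
                expected = 0 if qr <= 0.0 else int(n)
                pvals[r, s] = 1.0 if k == expected else 0.0
                continue
            pvals[r, s] = sps.binomtest(k, int(n), qr).pvalue
    masked = pvals >= alpha if alpha < 1.0 else np.zeros_like(pvals, dtype=bool)
    return LogoMatrix(diff=diff, pvals=pvals, masked=masked,
                      subsites=list(matrix.subsites), alpha=alpha)


def _save_figure(fig: plt.Figure, path_prefix: Path) -> list[Path]:
    written = []
    for ext in ("png", "svg"):
        out = path_prefix.with_suffix(f".{ext}")
        # Date metadata is suppressed so re-rendering is byte-identical.
        fig.savefig(out, metadata={"Date": None} if ext == "svg" else None, dpi=150)
        written.append(out)
    plt.close(fig)
    return written


def render_heatmap(
    matrix: SpecificityMatrix | PairMatrix,
    layer: str,
    path_prefix: str | Path,
    title: str | None = None,
) -> list[Path]:
    """Render a residue × subsite (or P2 × P1 pair) matrix layer as PNG and
    SVG heatmaps.

    Residues run down the rows alphabetically; subsites run P6→P5' across
    the columns.  Signed layers (Z-scores, differences) use a diverging
    colormap centred at zero, count-like layers a sequential one.
    """
    if isinstance(matrix, PairMatrix):
        values = matrix.layer_values()
        columns = list(AMINO_ACIDS)
        signed = matrix.layer == "zscore"
        xlabel, ylabel = "P1 residue", "P2 residue"
    else:
        if layer == "raw_count":
            values = matrix.counts.astype(float)
        elif layer == "frequency":
            values = matrix.frequencies
        elif layer == matrix.layer:
            values = matrix.layer_values()
        else:
            raise ValueError(f"matrix holds layer {matrix.layer!r}, not {layer!r}")
        columns = matrix.subsites
        signed = layer == "zscore"
        xlabel, ylabel = "subsite", "residue"
    finite = np.where(np.isfinite(values), values, 0.0)
    fig, ax = plt.subplots(figsize=(0.55 * len(columns) + 2.0, 7.0))
    if signed:
        vmax = float(np.abs(finite).max()) or 1.0
        mesh = ax.imshow(finite, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    else:
        mesh = ax.imshow(finite, cmap="Reds", aspect="auto")
    ax.set_xticks(range(len(columns)), columns, rotation=45 if len(columns) > 12 else 0)
    ax.set_yticks(range(len(AMINO_ACIDS)), list(AMINO_ACIDS))
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(title or layer)
    fig.colorbar(mesh, ax=ax, shrink=0.8)
    fig.tight_layout()
    return _save_figure(fig, Path(path_prefix))


def render_logo(logo: LogoMatrix, path_prefix: str | Path, title: str = "") -> list[Path]:
    """Render a percent-difference logo: per subsite, significant residues
    stacked as letters scaled by |difference| — enriched above the axis,
    depleted below."""
    fig, ax = plt.subplots(figsize=(0.9 * len(logo.subsites) + 1.5, 5.0))
    for s, label in enumerate(logo.subsites):
        ups = sorted(
            [(logo.diff[r, s], AMINO_ACIDS[r]) for r in range(len(AMINO_ACIDS))
             if not logo.masked[r, s] and logo.diff[r, s] > 0],
            reverse=True,
        )
        downs = sorted(
            [(logo.diff[r, s], AMINO_ACIDS[r]) for r in range(len(AMINO_ACIDS))
             if not logo.masked[r, s] and logo.diff[r, s] < 0],
        )
        y = 0.0
        for d, res in ups:
            ax.text(s, y + d / 2, res, ha="center", va="center",
                    fontsize=6 + min(d, 30) * 0.6, color="firebrick")
            y += d
        y = 0.0
        for d, res in downs:
            ax.text(s, y + d / 2, res, ha="center", va="center",
                    fontsize=6 + min(-d, 30) * 0.6, color="steelblue")
            y += d
    visible = np.where(logo.masked, 0.0, logo.diff)
    span = max(1.0, float(np.abs(visible).sum(axis=0).max()))
    ax.set_xlim(-0.7, len(logo.subsites) - 0.3)
    ax.set_ylim(-span, span)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xticks(range(len(logo.subsites)), logo.subsites)
    ax.set_ylabel("frequency difference (percentage points)")
    ax.set_title(title or f"percent-difference logo (p < {logo.alpha:g})")
    fig.tight_layout()
    return _save_figure(fig, Path(path_prefix))


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_report(
    outputs: Mapping[str, object],
    out_dir: str | Path,
    config: Mapping | None = None,
    render: bool = True,
) -> dict:
    """Write every stage output into one report directory with a
    machine-readable manifest.

    ``outputs`` maps a stage name to a supported object: SpecificityMatrix,
    PairMatrix, LogoMatrix, LengthSummary, MissedCleavageReport,
    BackgroundComposition, a pandas DataFrame, or any JSON-serialisable
    value.  Data artifacts are TSV/JSON; matrices additionally render to
    PNG + SVG when ``render`` is set.  The manifest records the effective
    config, software version and a SHA-256 checksum of every file, keyed
    by kind (``data`` vs ``image``), so reruns can be compared checksum by
    checksum.
    """
    from . import __version__

    if not outputs:
        raise ValueError("run_report needs at least one stage output")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}

    def _register(path: Path, kind: str) -> None:
        files[path.name] = {"kind": kind, "sha256": _sha256(path)}

    for name, obj in outputs.items():
        base = out_dir / name
        if isinstance(obj, SpecificityMatrix):
            obj.to_tsv(base.with_suffix(".tsv"))
            obj.to_json(base.with_suffix(".json"))
            _register(base.with_suffix(".tsv"), "data")
            _register(base.with_suffix(".json"), "data")
            if render:
                for p in render_heatmap(obj, obj.layer, base, title=name):
                    _register(p, "image")
        elif isinstance(obj, PairMatrix):
            obj.to_tsv(base.with_suffix(".tsv"))
            _register(base.with_suffix(".tsv"), "data")
            if render:
                for p in render_heatmap(obj, obj.layer, base, title=name):
                    _register(p, "image")
        elif isinstance(obj, LogoMatrix):
            frame_path = base.with_suffix(".tsv")
            import pandas as pd

            pd.DataFrame(obj.diff, index=list(AMINO_ACIDS), columns=obj.subsites).to_csv(
                frame_path, sep="\t", index_label="residue", float_format="%.10g"
            )
            _register(frame_path, "data")
            if render:
                for p in render_logo(obj, base, title=name):
                    _register(p, "image")
        elif isinstance(obj, (LengthSummary, MissedCleavageReport)):
            base.with_suffix(".json").write_text(json.dumps(obj.to_dict(), indent=1))
            _register(base.with_suffix(".json"), "data")
        elif isinstance(obj, BackgroundComposition):
            obj.to_tsv(base.with_suffix(".tsv"))
            _register(base.with_suffix(".tsv"), "data")
        else:
            try:
                import pandas as pd

                if isinstance(obj, pd.DataFrame):
                    obj.to_csv(base.with_suffix(".tsv"), sep="\t", index=False,
                               float_format="%.10g")
                    _register(base.with_suffix(".tsv"), "data")
                    continue
            except ImportError:  # pragma: no cover
                pass
            base.with_suffix(".json").write_text(json.dumps(obj, indent=1, default=str))
            _register(base.with_suffix(".json"), "data")

    manifest = {
        "software": {"name": "cleavemap", "version": __version__},
        "config": dict(config or {}),
        "files": dict(sorted(files.items())),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("report written to %s (%d files)", out_dir, len(files))
    return manifest
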