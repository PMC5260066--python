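"""Synthetic MRS layer: FID generation, canonical file formats, tracked
processing plugins, and a transparent mock quantitation.

The signal model is a sum of damped complex exponentials — the standard
time-domain description of an in-vivo MRS free induction decay:

    s(t_k) = sum_m  a_m * exp((i*2*pi*f_m - d_m) * t_k) + noise,

where each metabolite m contributes an amplitude ``a_m`` (proportional to
concentration), a frequency offset ``f_m`` [Hz] and a Lorentzian damping
``d_m`` [1/s]; ``t_k = k * dt`` with the sampling interval given in ms.
Noise is circular complex Gaussian with the given per-component standard
deviation.

Everything here is deliberately simple and exactly reproducible: the file
formats are canonical text (fixed 17-significant-digit floats, ``\\n``
endings), so identical datasets always serialize to identical bytes and
therefore identical SHA-256 hashes — the property the tracker's
deduplication and replay checks rest on. The quantitation is a linear
least-squares fit of the FID on the basis signals, a transparent stand-in
for a real spectral fitting algorithm: the tracker only ever sees its
provenance shape (two file parameters, one result file), which is the part
that matters here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .action_recorder import ParamSpec, ProvenanceEntry
from .errors import ExecutionError, ParseError, ValidationError
from .macro_engine import PluginRegistry, PluginSpec, register_plugin

FID_HEADER = "SpectraTrack FID v1"

#: Macro keys of the built-in preprocessing plugins, with their signatures.
PLUGIN_SIGNATURES: dict[str, tuple[tuple[str, str], ...]] = {
    "ZERO_FILL": ((("target length [points]"), "number"),),
    "APODIZE": ((("exponential line broadening [Hz]"), "number"),),
    "PHASE0": ((("zero-order phase [deg]"), "number"),),
    "SCALE": ((("scaling factor [dimensionless]"), "number"),),
}

QUANT_KEY = "QUANTIFY"
QUANT_SIGNATURE: tuple[tuple[str, str], ...] = (
    ("Metabolite list file [.ml]", "file"),
    ("Processing options file [.op]", "file"),
)


def _fmt(x: float) -> str:
    """Canonical float rendering: lowercase e, 17 significant digits."""
    return format(float(x), ".16e")


# ---------------------------------------------------------------------------
# domain types


@dataclass
class FidDataset:
    """A complex time-domain signal plus minimal acquisition metadata."""

    points: np.ndarray  # complex128, shape (n,)
    sampling_interval: float  # ms per point
    transmitter_frequency: float  # MHz
    label: str = "fid"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.complex128)
        if self.points.ndim != 1 or self.points.size == 0:
            raise ValidationError("FID must be a non-empty 1-D complex series")
        if not self.sampling_interval > 0:
            raise ValidationError("sampling interval must be positive")

    @property
    def n_points(self) -> int:
        return int(self.points.size)

    @property
    def time_axis_s(self) -> np.ndarray:
        """t_k = k * dt, in seconds (dt stored in ms)."""
        return np.arange(self.n_points) * (self.sampling_interval * 1e-3)

    def copy_with(self, points: np.ndarray) -> "FidDataset":
        return FidDataset(
            points=np.asarray(points, dtype=np.complex128),
            sampling_interval=self.sampling_interval,
            transmitter_frequency=self.transmitter_frequency,
            label=self.label,
        )


@dataclass(frozen=True)
class MetaboliteBasisEntry:
    """One metabolite's reference signal: frequency offset and damping."""

    name: str
    frequency_hz: float
    damping_hz: float  # Lorentzian decay rate, >= 0

    def __post_init__(self) -> None:
        if not str(self.name).strip():
            raise ValidationError("metabolite name must be non-empty")
        if self.damping_hz < 0:
            raise ValidationError("damping must be non-negative")


@dataclass(frozen=True)
class QuantResult:
    """Mock-quantitation output: per-metabolite amplitudes + residual norm."""

    amplitudes: tuple[tuple[str, float], ...]
    residual_norm: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.amplitudes)


# ---------------------------------------------------------------------------
# signal generation


def basis_signal_matrix(
    basis: Sequence[MetaboliteBasisEntry], n_points: int, sampling_interval: float
) -> np.ndarray:
    """Design matrix A with A[k, m] = exp((i*2*pi*f_m - d_m) * t_k)."""
    t = np.arange(n_points) * (sampling_interval * 1e-3)
    rates = np.array(
        [2j * np.pi * b.frequency_hz - b.damping_hz for b in basis], dtype=np.complex128
    )
    return np.exp(np.outer(t, rates))


def generate_fid(
    basis: Sequence[MetaboliteBasisEntry],
    amplitudes: Sequence[float],
    n_points: int = 512,
    sampling_interval: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    transmitter_frequency: float = 63.86,
    label: str = "synthetic",
) -> FidDataset:
    """Simulate an FID from a metabolite basis, fully seeded.

    Noise is complex Gaussian with standard deviation ``noise_sd`` per real
    and imaginary component; a fixed seed gives bit-identical output.
    """
    if n_points < 2:
        raise ValidationError("n_points must be at least 2")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if len(amplitudes) != len(basis):
        raise ValidationError(
            f"{len(basis)} basis entries but {len(amplitudes)} amplitudes"
        )
    _check_unique_names(basis)
    A = basis_signal_matrix(basis, n_points, sampling_interval)
    signal = A @ np.asarray(amplitudes, dtype=np.float64)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + noise_sd * (
            rng.standard_normal(n_points) + 1j * rng.standard_normal(n_points)
        )
    return FidDataset(
        points=signal,
        sampling_interval=sampling_interval,
        transmitter_frequency=transmitter_frequency,
        label=label,
    )


def _check_unique_names(basis: Sequence[MetaboliteBasisEntry]) -> None:
    names = [b.name for b in basis]
    if len(set(names)) != len(names):
        raise ValidationError("metabolite names must be unique within a basis")


# ---------------------------------------------------------------------------
# canonical serialization


def write_fid(dataset: FidDataset, path: str | Path) -> Path:
    """Serialize canonically: write∘read∘write is byte-identical."""
    lines = [
        FID_HEADER,
        f"PointsInDataset: {dataset.n_points}",
        f"SamplingInterval_ms: {_fmt(dataset.sampling_interval)}",
        f"TransmitterFrequency_MHz: {_fmt(dataset.transmitter_frequency)}",
        f"Label: {dataset.label}",
        "Data:",
    ]
    lines.extend(
        f"{_fmt(p.real)}\t{_fmt(p.imag)}" for p in dataset.points
    )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_fid(path: str | Path) -> FidDataset:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != FID_HEADER:
        raise ParseError(f"not a {FID_HEADER!r} file", line=1)

    def header(idx: int, key: str) -> str:
        if idx >= len(lines) or not lines[idx].startswith(key + ": "):
            raise ParseError(f"expected {key!r} header", line=idx + 1)
        return lines[idx][len(key) + 2 :]

    try:
        n = int(header(1, "PointsInDataset"))
        dt = float(header(2, "SamplingInterval_ms"))
        tf = float(header(3, "TransmitterFrequency_MHz"))
    except ValueError as exc:
        raise ParseError(f"malformed numeric header: {exc}", line=2) from exc
    label = header(4, "Label")
    if len(lines) < 6 or lines[5] != "Data:":
        raise ParseError("expected 'Data:' section", line=6)
    data_lines = lines[6:]
    if len(data_lines) != n:
        raise ParseError(
            f"expected {n} data lines, found {len(data_lines)}", line=7
        )
    points = np.empty(n, dtype=np.complex128)
    for k, row in enumerate(data_lines):
        parts = row.split("\t")
        if len(parts) != 2:
            raise ParseError("data line must be 'real<TAB>imag'", line=7 + k)
        try:
            points[k] = complex(float(parts[0]), float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"non-numeric sample: {exc}", line=7 + k) from exc
    return FidDataset(points=points, sampling_interval=dt,
                      transmitter_frequency=tf, label=label)


def write_basis(entries: Sequence[MetaboliteBasisEntry], path: str | Path) -> Path:
    _check_unique_names(entries)
    path = Path(path)
    path.write_text(
        "".join(
            f"{b.name}\t{_fmt(b.frequency_hz)}\t{_fmt(b.damping_hz)}\n"
            for b in entries
        ),
        encoding="utf-8",
    )
    return path


def read_basis(path: str | Path) -> list[MetaboliteBasisEntry]:
    entries: list[MetaboliteBasisEntry] = []
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 3:
            raise ParseError("basis line must be 'name<TAB>freq<TAB>damping'", line=lineno)
        try:
            entries.append(
                MetaboliteBasisEntry(parts[0], float(parts[1]), float(parts[2]))
            )
        except ValueError as exc:
            raise ParseError(f"non-numeric basis value: {exc}", line=lineno) from exc
    if not entries:
        raise ValidationError(f"basis file {path} is empty")
    _check_unique_names(entries)
    return entries


def write_options(options: Mapping[str, float], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        "".join(f"{k}: {_fmt(v)}\n" for k, v in options.items()), encoding="utf-8"
    )
    return path


def read_options(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not raw.strip():
            continue
        if ": " not in raw:
            raise ParseError("options line must be 'key: value'", line=lineno)
        key, value = raw.split(": ", 1)
        try:
            out[key] = float(value)
        except ValueError as exc:
            raise ParseError(f"non-numeric option value: {exc}", line=lineno) from exc
    return out


def write_quant_result(result: QuantResult, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        "".join(f"{name}\t{_fmt(a)}\n" for name, a in result.amplitudes),
        encoding="utf-8",
    )
    return path


def read_quant_result(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 2:
            raise ParseError("result line must be 'name<TAB>amplitude'", line=lineno)
        out[parts[0]] = float(parts[1])
    return out


# ---------------------------------------------------------------------------
# processing plugins


def apply_processing(
    key: str, dataset: FidDataset, params: Sequence[float]
) -> tuple[FidDataset, ProvenanceEntry]:
    """Apply one deterministic preprocessing operator.

    ZERO_FILL appends zeros up to the target length; APODIZE multiplies by
    ``exp(-pi * lb * t)``; PHASE0 multiplies by ``exp(i * phi)``; SCALE
    multiplies by a constant. Returns the transformed dataset together with
    the provenance entry describing exactly what was applied.
    """
    if key not in PLUGIN_SIGNATURES:
        raise ValidationError(f"unknown processing key {key!r}")
    signature = PLUGIN_SIGNATURES[key]
    if len(params) != len(signature):
        raise ValidationError(
            f"{key} expects {len(signature)} parameter(s), got {len(params)}"
        )
    value = float(params[0])

    if key == "ZERO_FILL":
        target = int(round(value))
        if target < dataset.n_points:
            raise ValidationError(
                f"ZERO_FILL target {target} is below current length {dataset.n_points}"
            )
        new_points = np.zeros(target, dtype=np.complex128)
        new_points[: dataset.n_points] = dataset.points
        out = dataset.copy_with(new_points)
        recorded = str(target)
    elif key == "APODIZE":
        if value < 0:
            raise ValidationError("line broadening must be non-negative")
        out = dataset.copy_with(
            dataset.points * np.exp(-np.pi * value * dataset.time_axis_s)
        )
        recorded = repr(value)
    elif key == "PHASE0":
        out = dataset.copy_with(dataset.points * np.exp(1j * np.deg2rad(value)))
        recorded = repr(value)
    else:  # SCALE
        if value == 0:
            raise ValidationError("scaling factor must be non-zero")
        out = dataset.copy_with(dataset.points * value)
        recorded = repr(value)

    entry = ProvenanceEntry(
        action=key,
        params=[ParamSpec(value=recorded, description=signature[0][0])],
    )
    return out, entry


# ---------------------------------------------------------------------------
# mock quantitation


def quantify(
    dataset: FidDataset,
    basis: Sequence[MetaboliteBasisEntry],
    zero_order_phase_deg: float = 0.0,
) -> QuantResult:
    """Linear least-squares amplitude fit of an FID on the basis signals.

    The zero-order phase from the options is applied to the data first;
    amplitudes are the real parts of the complex LS solution (the signal
    model has real amplitudes). Rank-deficient designs (e.g. duplicated
    basis signals) are rejected.
    """
    _check_unique_names(basis)
    y = dataset.points * np.exp(1j * np.deg2rad(zero_order_phase_deg))
    A = basis_signal_matrix(basis, dataset.n_points, dataset.sampling_interval)
    coeffs, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < len(basis):
        raise ExecutionError(
            "singular design: basis signals are linearly dependent"
        )
    residual = float(np.linalg.norm(y - A @ coeffs))
    return QuantResult(
        amplitudes=tuple((b.name, float(c.real)) for b, c in zip(basis, coeffs)),
        residual_norm=residual,
    )


def _sanitize_label(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", label) or "fid"


def mock_quantitation(
    dataset: FidDataset,
    basis_file_path: str | Path,
    options_file_path: str | Path,
    out_dir: str | Path | None = None,
) -> tuple[Path, ProvenanceEntry]:
    """Run the mock quantitation and emit its tracked provenance.

    Reads the metabolite basis (.ml) and options (.op) files, fits the
    amplitudes, writes ``<label>_QUANT.results`` (tab-separated
    name/amplitude lines) and returns the result path plus a quantitation
    provenance entry carrying both files as hashed file parameters —
    exactly the shape a real quantitation plugin hands the recorder.
    """
    basis_file_path = Path(basis_file_path)
    options_file_path = Path(options_file_path)
    basis = read_basis(basis_file_path)
    options = read_options(options_file_path)
    phase = options.get("ZeroOrderPhase_deg", 0.0)
    result = quantify(dataset, basis, zero_order_phase_deg=phase)

    out_dir = Path(out_dir) if out_dir is not None else basis_file_path.parent
    result_path = out_dir / f"{_sanitize_label(dataset.label)}_QUANT.results"
    write_quant_result(result, result_path)

    entry = ProvenanceEntry(
        action=QUANT_KEY,
        params=[
            ParamSpec(
                value=str(basis_file_path.resolve()),
                description=QUANT_SIGNATURE[0][0],
                is_file=True,
            ),
            ParamSpec(
                value=str(options_file_path.resolve()),
                description=QUANT_SIGNATURE[1][0],
                is_file=True,
            ),
        ],
        is_quantitation=True,
        result_path=result_path,
    )
    return result_path, entry


# ---------------------------------------------------------------------------
# plugin registry wiring


def build_default_plugins(quant_out_dir: str | Path | None = None) -> PluginRegistry:
    """Registry with the four preprocessing plugins plus the quantitation.

    ``quant_out_dir`` is where replayed quantitations write their result
    files (defaults next to the basis file).
    """
    registry = PluginRegistry()
    for key, signature in PLUGIN_SIGNATURES.items():
        def make(k):
            def run(dataset, value):
                return apply_processing(k, dataset, [value])
            return run
        register_plugin(
            registry,
            PluginSpec(key=key, signature=signature, func=make(key)),
        )

    def run_quant(dataset, basis_path, options_path):
        return mock_quantitation(
            dataset, basis_path, options_path, out_dir=quant_out_dir
        )

    register_plugin(
        registry,
        PluginSpec(
            key=QUANT_KEY,
            signature=QUANT_SIGNATURE,
            func=run_quant,
            is_quantitation=True,
        ),
    )
    return registry


# ---------------------------------------------------------------------------
# demo session


#: Study-style defaults for the demo acquisition: three brain metabolites
#: with MRS-plausible offsets/linewidths at 1.5 T, 512 points at 0.5 ms,
#: mild noise.
DEMO_BASIS = (
    MetaboliteBasisEntry("NAA", -97.0, 8.0),
    MetaboliteBasisEntry("Cr", -146.0, 10.0),
    MetaboliteBasisEntry("Cho", -151.5, 9.0),
)
DEMO_AMPLITUDES = (2.0, 1.0, 0.6)
DEMO_N_POINTS = 512
DEMO_SAMPLING_INTERVAL_MS = 0.5
DEMO_NOISE_SD = 0.01
DEMO_APODIZE_LB_HZ = 5.0
DEMO_PHASE0_DEG = 30.0
DEMO_MACRO_NAME = "demo-preprocessing"


def run_demo_session(
    store_dir: str | Path, work_dir: str | Path, seed: int = 0
) -> dict:
    """Scripted end-to-end session exercising every tracking feature.

    Initializes a store; generates and writes a synthetic FID plus basis
    and options files; loads the data; applies APODIZE and PHASE0; runs the
    mock quantitation; saves the processed file (recording lineage);
    records the two preprocessing steps as a macro; and exports the
    reproducibility bundle for the result. Returns a summary with the
    per-table row counts, the file/result hashes, the bundle manifest and
    the ids needed to replay the session.
    """
    from .action_recorder import record_action
    from .file_registry import (
        OpenFilesRegistry,
        compute_file_hash,
        file_record,
        register_loaded_file,
        register_saved_file,
    )
    from .history_query import export_result_bundle
    from .macro_engine import create_macro
    from .schema_store import init_store, scripted_clock

    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)

    # scripted session: a deterministic clock keeps the rendered history
    # (and therefore the bundle bytes) identical across reruns
    store = init_store(store_dir, clock=scripted_clock())
    registry = OpenFilesRegistry()

    # The fitted basis carries the extra damping the APODIZE step introduces
    # (exp(-pi*lb*t) adds pi*lb to each decay rate), so the demo's amplitude
    # estimates land near the generating values instead of being biased by
    # the line broadening.
    quant_basis = [
        MetaboliteBasisEntry(
            b.name, b.frequency_hz, b.damping_hz + np.pi * DEMO_APODIZE_LB_HZ
        )
        for b in DEMO_BASIS
    ]
    basis_path = write_basis(quant_basis, work_dir / "basis.ml")
    options_path = write_options(
        {"ZeroOrderPhase_deg": -DEMO_PHASE0_DEG}, work_dir / "quant.op"
    )
    dataset = generate_fid(
        DEMO_BASIS,
        DEMO_AMPLITUDES,
        n_points=DEMO_N_POINTS,
        sampling_interval=DEMO_SAMPLING_INTERVAL_MS,
        noise_sd=DEMO_NOISE_SD,
        seed=seed,
        label="demo",
    )
    data_path = write_fid(dataset, work_dir / "data.fid")

    id_original = register_loaded_file(store, registry, data_path)

    dataset, entry = apply_processing("APODIZE", dataset, [DEMO_APODIZE_LB_HZ])
    aid_apodize = record_action(store, registry, entry, [id_original])

    dataset, entry = apply_processing("PHASE0", dataset, [DEMO_PHASE0_DEG])
    aid_phase = record_action(store, registry, entry, [id_original])

    result_path, entry = mock_quantitation(
        dataset, basis_path, options_path, out_dir=work_dir
    )
    aid_quant = record_action(store, registry, entry, [id_original])

    processed_path = write_fid(dataset, work_dir / "processed.fid")
    id_saved = register_saved_file(store, registry, id_original, processed_path)

    id_macro = create_macro(
        store,
        DEMO_MACRO_NAME,
        "apodization + zero-order phase of the demo session",
        [aid_apodize, aid_phase],
    )

    result_hash = compute_file_hash(result_path)
    bundle_path = work_dir / "bundle.zip"
    manifest = export_result_bundle(store, result_hash, bundle_path)

    summary = {
        "store_dir": str(Path(store_dir)),
        "row_counts": store.row_counts(),
        "id_file_original": id_original,
        "id_file_saved": id_saved,
        "id_macro": id_macro,
        "action_ids": {
            "APODIZE": aid_apodize,
            "PHASE0": aid_phase,
            QUANT_KEY: aid_quant,
        },
        "data_path": str(data_path),
        "data_hash": compute_file_hash(data_path),
        "saved_path": str(processed_path),
        "saved_hash": file_record(store, id_saved).hash,
        "result_path": str(result_path),
        "result_hash": result_hash,
        "amplitude_estimates": read_quant_result(result_path),
        "bundle_path": str(bundle_path),
        "manifest": manifest,
    }
    store.close()
    return summary
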