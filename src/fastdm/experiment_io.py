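"""Control-file driven batch estimation: the command-line contract.

A *control file* is a plain-text list of commands (``method``,
``precision``, ``set``, ``depends``, ``format``, ``load``, ``save``,
``log``) that defines the model, the data-file layout and the output
destinations.  *Data files* are whitespace-delimited, one trial per
line, with mandatory RESPONSE (0/1) and TIME (seconds) columns and
arbitrary condition columns; ``#`` starts a comment line in both file
kinds.
"""

from __future__ import annotations

import argparse
import fnmatch
import glob
import itertools
import re
import sys
import time
from dataclasses import dataclass, field

import numpy as np

from .errors import (ControlFileError, DataFileError, EstimationError,
                     TrialMinimumError)
from .fit_criteria import Dataset
from .model_core import PARAM_NAMES, ParameterSet

__all__ = [
    "ExperimentSpec", "ParameterTable", "Slot",
    "parse_control_file", "read_data_file", "expand_wildcards",
    "resolve_save_name", "check_trial_minimums", "build_parameter_table",
    "write_outputs", "run_experiment", "main",
]

_MIN_TRIALS_ML_KS = 10
_MIN_TRIALS_CS = 12


@dataclass
class ExperimentSpec:
    """Parsed control file."""

    method: str = "ks"
    precision: float = 3.0
    fixed: dict = field(default_factory=dict)
    depends: dict = field(default_factory=dict)   # param -> tuple of labels
    format: tuple = ()
    loads: list = field(default_factory=list)
    save: str | None = None
    log: str | None = None

    @property
    def condition_labels(self) -> tuple:
        """Format columns that name conditions (not RESPONSE/TIME/ignored)."""
        return tuple(c for c in self.format
                     if c not in ("RESPONSE", "TIME") and not c.startswith("*"))


def parse_control_file(text: str) -> ExperimentSpec:
    """Parse control-file text, applying defaults and checking consistency.

    Command order is enforced: ``set``/``depends`` must precede
    ``format``; ``load``/``save``/``log`` must follow it.  Any
    malformed command aborts with :class:`ControlFileError`.
    """
    spec = ExperimentSpec()
    seen_format = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        cmd, args = parts[0], parts[1:]

        def err(msg):
            raise ControlFileError(f"line {lineno}: {msg} ({raw.strip()!r})")

        if cmd == "method":
            if len(args) != 1 or args[0] not in ("ml", "ks", "cs"):
                err("method must be one of ml, ks, cs")
            spec.method = args[0]
        elif cmd == "precision":
            try:
                spec.precision = float(args[0])
            except (IndexError, ValueError):
                err("precision needs a numeric value")
            if not spec.precision > 0:
                err("precision must be positive")
        elif cmd == "set":
            if seen_format:
                err("set commands must precede the format command")
            if len(args) != 2 or args[0] not in PARAM_NAMES:
                err(f"set needs a parameter name in {PARAM_NAMES} and a value")
            try:
                spec.fixed[args[0]] = float(args[1])
            except ValueError:
                err("set needs a numeric value")
        elif cmd == "depends":
            if seen_format:
                err("depends commands must precede the format command")
            if len(args) < 2 or args[0] not in PARAM_NAMES:
                err("depends needs a parameter name and at least one condition label")
            spec.depends[args[0]] = tuple(args[1:])
        elif cmd == "format":
            if seen_format:
                err("only one format command is allowed")
            if not args:
                err("format needs column labels")
            seen_format = True
            spec.format = tuple(args)
        elif cmd in ("load", "save", "log"):
            if not seen_format:
                err(f"{cmd} must come after the format command")
            if not args:
                err(f"{cmd} needs a file name")
            name = " ".join(args)
            if cmd == "load":
                spec.loads.append(name)
            elif cmd == "save":
                spec.save = name
            else:
                spec.log = name
        else:
            err(f"unknown command {cmd!r}")

    if not seen_format:
        raise ControlFileError("missing required format command")
    if "RESPONSE" not in spec.format or "TIME" not in spec.format:
        raise ControlFileError("format must name the RESPONSE and TIME columns")
    if not spec.loads:
        raise ControlFileError("missing required load command")
    if spec.save is None and spec.log is None:
        raise ControlFileError("either a save or a log command is required")
    both = set(spec.fixed) & set(spec.depends)
    if both:
        raise ControlFileError(
            f"parameters cannot be both set and depends: {sorted(both)}")
    labels = set(spec.condition_labels)
    for param, deps in spec.depends.items():
        missing = [l for l in deps if l not in labels]
        if missing:
            raise ControlFileError(
                f"depends {param}: condition label(s) {missing} not named "
                f"in the format command")
    if spec.save is not None and "*" not in spec.save \
            and any("*" in l for l in spec.loads):
        raise ControlFileError(
            "load uses a wildcard, so the save file name needs an "
            "asterisk to disambiguate the outputs")
    return spec


def read_data_file(path: str, fmt) -> Dataset:
    """Read one whitespace-delimited trial file according to ``format``."""
    fmt = tuple(fmt)
    i_resp = fmt.index("RESPONSE")
    i_time = fmt.index("TIME")
    cond_cols = [(i, label) for i, label in enumerate(fmt)
                 if label not in ("RESPONSE", "TIME") and not label.startswith("*")]
    responses, rts, conditions = [], [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) != len(fmt):
                raise DataFileError(
                    f"{path}:{lineno}: expected {len(fmt)} columns, "
                    f"found {len(toks)}")
            if toks[i_resp] not in ("0", "1"):
                raise DataFileError(
                    f"{path}:{lineno}: RESPONSE must be 0 or 1, "
                    f"got {toks[i_resp]!r}")
            try:
                rt = float(toks[i_time])
            except ValueError:
                raise DataFileError(
                    f"{path}:{lineno}: TIME is not numeric: {toks[i_time]!r}")
            if not np.isfinite(rt) or rt <= 0:
                raise DataFileError(
                    f"{path}:{lineno}: TIME must be a positive number of "
                    f"seconds, got {rt!r}")
            responses.append(int(toks[i_resp]))
            rts.append(rt)
            conditions.append([toks[i] for i, _ in cond_cols])
    labels = tuple(label for _, label in cond_cols)
    cond = np.array(conditions, dtype=object) if conditions \
        else np.empty((0, len(labels)), dtype=object)
    return Dataset(np.array(responses, int), np.array(rts, float),
                   cond, labels, name=path)


def expand_wildcards(pattern: str) -> list[str]:
    """Matching paths in deterministic lexicographic order."""
    matches = sorted(glob.glob(pattern))
    if not matches:
        raise DataFileError(f"no files match {pattern!r}")
    return matches


def resolve_save_name(save_pattern: str, load_pattern: str, path: str) -> str:
    """Substitute the load-wildcard match into the save pattern."""
    if "*" not in load_pattern:
        return save_pattern
    rx = "^" + "(.*)".join(re.escape(part)
                           for part in load_pattern.split("*")) + "$"
    m = re.match(rx, path)
    fragment = "_".join(m.groups()) if m else path
    return save_pattern.replace("*", fragment)


def check_trial_minimums(dataset: Dataset, method: str, cell_labels=(),
                         cells=None) -> None:
    """Abort estimation when a condition has too few trials.

    ml/ks need at least 10 trials per condition; cs needs at least one
    response given in 12 or more trials per condition.
    """
    groups = dataset.group_cells(cell_labels)
    keys = cells if cells is not None else list(groups)
    for key in keys:
        idx = groups.get(tuple(key), np.array([], dtype=int))
        label = " ".join(map(str, key)) if key else "the single condition"
        if method in ("ml", "ks"):
            if len(idx) < _MIN_TRIALS_ML_KS:
                raise TrialMinimumError(
                    f"condition {label}: {len(idx)} trials, but the "
                    f"{method} criterion requires at least "
                    f"{_MIN_TRIALS_ML_KS} per condition")
        elif method == "cs":
            resp = dataset.responses[idx]
            n_major = max(int((resp == 1).sum()), int((resp == 0).sum())) \
                if len(idx) else 0
            if n_major < _MIN_TRIALS_CS:
                raise TrialMinimumError(
                    f"condition {label}: no response was given in at least "
                    f"{_MIN_TRIALS_CS} trials, as the cs criterion requires")
        else:
            raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class Slot:
    """One free-parameter slot: shared, or specific to a label combination."""

    name: str
    param: str
    subkey: tuple | None  # None = shared across conditions


@dataclass
class ParameterTable:
    """Mapping between condition cells, slots, and full parameter sets."""

    slots: list
    fixed: dict
    depends: dict
    labels: tuple           # all labels used by any depends, format order
    level_sets: dict        # label -> tuple of observed levels (sorted)
    cells: list             # full Cartesian product, row-major in label order

    @property
    def n_free(self) -> int:
        return len(self.slots)

    @property
    def slot_names(self) -> list[str]:
        return [s.name for s in self.slots]

    def _index(self) -> dict:
        return {(s.param, s.subkey): i for i, s in enumerate(self.slots)}

    def expand(self, x) -> dict[tuple, ParameterSet]:
        """Resolve every condition cell to a full ParameterSet."""
        x = np.asarray(x, float)
        idx = self._index()
        out = {}
        for cell in self.cells:
            kwargs = {}
            for param in PARAM_NAMES:
                if param in self.fixed:
                    kwargs[param] = self.fixed[param]
                elif param in self.depends:
                    sub = tuple(cell[self.labels.index(l)]
                                for l in self.depends[param])
                    kwargs[param] = float(x[idx[(param, sub)]])
                else:
                    kwargs[param] = float(x[idx[(param, None)]])
            out[cell] = ParameterSet(**kwargs)
        return out


def build_parameter_table(spec: ExperimentSpec, dataset: Dataset) -> ParameterTable:
    """Expand the model definition against the levels observed in data.

    Condition cells are the Cartesian product of the observed level sets
    of every label named in any ``depends`` command; a parameter that
    depends on conditions gets one free slot per combination of *its*
    labels, everything else one shared slot, and ``set`` parameters none.
    """
    labels = tuple(l for l in spec.condition_labels
                   if any(l in deps for deps in spec.depends.values()))
    level_sets = {}
    for label in labels:
        col = dataset.labels.index(label) if label in dataset.labels else None
        if col is None:
            raise ControlFileError(
                f"condition label {label!r} missing from the dataset")
        levels = sorted({str(v) for v in dataset.conditions[:, col]})
        if not levels:
            raise EstimationError(f"no observed levels for label {label!r}")
        level_sets[label] = tuple(levels)

    cells = [tuple(c) for c in itertools.product(
        *(level_sets[l] for l in labels))] or [()]

    slots = []
    for param in PARAM_NAMES:
        if param in spec.fixed:
            continue
        if param in spec.depends:
            deps = spec.depends[param]
            for combo in itertools.product(*(level_sets[l] for l in deps)):
                slots.append(Slot(name="_".join((param,) + combo),
                                  param=param, subkey=tuple(combo)))
        else:
            slots.append(Slot(name=param, param=param, subkey=None))
    return ParameterTable(slots=slots, fixed=dict(spec.fixed),
                          depends=dict(spec.depends), labels=labels,
                          level_sets=level_sets, cells=cells)


# ----------------------------------------------------------------------
# output

def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _fit_label(method: str) -> str:
    return {"ml": "-LL", "cs": "CS", "ks": "p(KS)"}[method]


def format_save_text(result, spec: ExperimentSpec) -> str:
    """Per-dataset output file: a short version of the console report."""
    lines = [f"# dataset {result.dataset}",
             f"method {spec.method}",
             f"precision {_fmt(spec.precision)}"]
    for name, value in result.estimates.items():
        lines.append(f"{name} = {_fmt(value)}")
    for param, value in spec.fixed.items():
        lines.append(f"{param} = {_fmt(value)} (fixed)")
    if result.penalized:
        lines.append(f"penalty = {_fmt(result.penalty)}")
    else:
        lines.append(f"fit index ({_fit_label(spec.method)}) = "
                     f"{_fmt(result.fit_index.value)}")
    return "\n".join(lines) + "\n"


def format_log_table(results, spec: ExperimentSpec) -> str:
    """Common tab-separated table: one row per dataset."""
    if not results:
        raise ValueError("no results to log")
    slot_names = list(results[0].estimates)
    header = ["dataset"] + slot_names + ["fit", "penalized"]
    rows = ["\t".join(header)]
    for r in results:
        fitval = r.penalty if r.penalized else r.fit_index.value
        row = [r.dataset] + [_fmt(r.estimates[s]) for s in slot_names] \
            + [_fmt(fitval), "1" if r.penalized else "0"]
        rows.append("\t".join(row))
    return "\n".join(rows) + "\n"


def write_outputs(results, spec: ExperimentSpec, save_paths=None) -> None:
    """Write save files (one per dataset) and/or the common log file."""
    if spec.save is not None:
        for result, path in zip(results, save_paths):
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(format_save_text(result, spec))
    if spec.log is not None:
        with open(spec.log, "w", encoding="utf-8") as fh:
            fh.write(format_log_table(results, spec))


def _check_writable(path: str) -> None:
    import os
    probe = path.replace("*", "probe")
    existed = os.path.exists(probe)
    try:
        with open(probe, "a", encoding="utf-8"):
            pass
    except OSError as exc:
        raise ControlFileError(f"output path {path!r} is not writable: {exc}")
    if not existed:
        os.remove(probe)


def _console_report(result, dataset, table, out) -> None:
    print(f"dataset {result.dataset}: {dataset.n} trials", file=out)
    groups = dataset.group_cells(table.labels)
    for key, idx in groups.items():
        resp = dataset.responses[idx]
        label = " ".join(map(str, key)) if key else "(all)"
        print(f"  condition {label}: {(resp == 0).sum()} lower / "
              f"{(resp == 1).sum()} upper responses", file=out)
    vals = "  ".join(_fmt(v) for v in result.run_values)
    print(f"  {_fit_label(result.method)} over the three runs: {vals}", file=out)
    for name, value in result.estimates.items():
        print(f"  {name} = {_fmt(value)}", file=out)
    if result.penalized:
        print(f"  WARNING: no valid solution, penalty = {_fmt(result.penalty)}",
              file=out)


def run_experiment(spec: ExperimentSpec, out=None):
    """Load every data file, fit it, report, and write the outputs."""
    from .optimizer import fit  # deferred: optimizer imports this module

    if out is None:
        out = sys.stdout
    if spec.save is not None:
        _check_writable(spec.save)
    if spec.log is not None:
        _check_writable(spec.log)

    files = []
    for pattern in spec.loads:
        files.extend(expand_wildcards(pattern))

    t_start = time.perf_counter()
    print(f"method {spec.method}, precision {_fmt(spec.precision)}", file=out)
    print(f"format {' '.join(spec.format)}", file=out)

    results, save_paths = [], []
    for path in files:
        dataset = read_data_file(path, spec.format)
        table = build_parameter_table(spec, dataset)
        try:
            result = fit(dataset, spec, table=table)
        except TrialMinimumError as exc:
            print(f"WARNING: {exc}", file=out)
            print("estimation process stopped", file=out)
            return None
        _console_report(result, dataset, table, out)
        results.append(result)
        if spec.save is not None:
            load_pat = next((p for p in spec.loads
                             if fnmatch.fnmatch(path, p)), spec.loads[0])
            save_paths.append(resolve_save_name(spec.save, load_pat, path))

    write_outputs(results, spec, save_paths)
    dt = time.perf_counter() - t_start
    print(f"{len(results)} data set(s) processed in {dt:.1f} s", file=out)
    return results


def main(argv=None) -> int:
    """Entry point of the ``fast-dm`` command."""
    parser = argparse.ArgumentParser(
        prog="fast-dm",
        description="Estimate diffusion-model parameters from response-time "
                    "data as directed by a control file.")
    parser.add_argument("control_file", nargs="?", default="experiment.ctl",
                        help="control file (default: experiment.ctl)")
    parser.add_argument("--seed", type=int, default=None,
                        help="seed for any stochastic internals (reserved; "
                             "estimation itself is deterministic)")
    args = parser.parse_args(argv)
    try:
        with open(args.control_file, encoding="utf-8") as fh:
            spec = parse_control_file(fh.read())
        print(f"control file: {args.control_file}")
        results = run_experiment(spec)
    except (ControlFileError, DataFileError, EstimationError) as exc:
        print(f"ERROR: {exc}", file=sys.stderr)
        return 1
    except FileNotFoundError as exc:
        print(f"ERROR: {exc}", file=sys.stderr)
        return 1
    return 0 if results is not None else 1


if __name__ == "__main__":
    raise SystemExit(main())
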