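"""Result documents, trace files and optional plots.

Every run is serialized as a JSON document that echoes the full
configuration (including the seed), so any result can be reproduced from
its own output file.  Traces are plain CSV; plots are rendered only when a
plotting backend is importable and silently degrade to CSV-only otherwise.
"""

from __future__ import annotations

import csv
import json
import time
from pathlib import Path
from typing import Sequence

from .avatar import AvatarResult
from .firefront import FirefrontResult, TraceRow
from .stg import AbsorptionResult, Attractor

SCHEMA_VERSION = 1


def attractor_entry(att: Attractor, model=None) -> dict:
    states = sorted(att.states)
    entry: dict = {"type": att.kind}
    if model is not None:
        entry["states"] = [model.format_state(s) for s in states]
    else:
        entry["states"] = states
    return entry


def absorption_document(result: AbsorptionResult, model=None) -> list[dict]:
    out = []
    for att, prob in sorted(
        result.probabilities.items(), key=lambda kv: -kv[1]
    ):
        entry = attractor_entry(att, model)
        entry["probability"] = prob
        out.append(entry)
    return out


def firefront_document(result: FirefrontResult, model=None) -> dict:
    attractors = []
    for est in result.attractors:
        entry: dict = {"type": est.kind, "bounds": [est.lower, est.upper]}
        if est.name is not None:
            entry["oracle"] = est.name
        if est.states is not None:
            states = sorted(est.states)
            entry["states"] = (
                [model.format_state(s) for s in states] if model else states
            )
        attractors.append(entry)
    return {
        "attractors": attractors,
        "residualF": result.residual_f,
        "residualN": result.residual_n,
        "terminationReason": result.termination,
        "expansions": result.iterations,
    }


def avatar_document(result: AvatarResult, model=None) -> dict:
    attractors = []
    for est in result.attractors:
        entry: dict = {
            "type": est.kind,
            "probability": est.probability,
            "ci": list(est.ci),
            "meanDepth": est.mean_depth,
            "hits": est.hits,
        }
        if est.name is not None:
            entry["oracle"] = est.name
        if est.states is not None:
            states = sorted(est.states)
            entry["states"] = (
                [model.format_state(s) for s in states] if model else states
            )
        attractors.append(entry)
    return {
        "attractors": attractors,
        "runs": result.runs,
        "inconclusive": result.inconclusive,
        "support": result.support,
        "largestTransientSCC": result.largest_transient_scc,
    }


def result_document(algorithm: str, config: dict, results, seed, started: float) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "algorithm": algorithm,
        "config": config,
        "seed": seed,
        "results": results,
        "wallTimeSeconds": round(time.perf_counter() - started, 3),
    }


def write_document(doc: dict, path) -> None:
    text = json.dumps(doc, indent=1)
    if path in (None, "-"):
        print(text)
    else:
        Path(path).write_text(text + "\n")


# ---------------------------------------------------------------------------
# Traces


def write_firefront_trace(trace: Sequence[TraceRow], path) -> None:
    """CSV with one row per expansion: set sizes and set masses."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["iteration", "sizeF", "sizeN", "sizeA", "massF", "massN", "massA"]
        )
        for row in trace:
            writer.writerow(
                [
                    row.iteration,
                    row.size_f,
                    row.size_n,
                    row.size_a,
                    f"{row.mass_f:.12g}",
                    f"{row.mass_n:.12g}",
                    f"{row.mass_a:.12g}",
                ]
            )


def avatar_convergence(result: AvatarResult) -> tuple[list[str], list[list[float]]]:
    """Running per-attractor estimates after each simulation."""
    labels = [est.label for est in result.attractors]

    def label_for(kind: str, handle) -> str | None:
        for est in result.attractors:
            if est.kind != kind:
                continue
            if kind == "stable" and est.states == frozenset({handle}):
                return est.label
            if kind == "complex" and handle in est.states:
                return est.label
            if kind == "oracle" and est.name == handle:
                return est.label
        return None

    rows = []
    counts = {label: 0 for label in labels}
    for i, (kind, handle) in enumerate(result.outcomes, start=1):
        label = None if kind == "inconclusive" else label_for(kind, handle)
        if label is not None:
            counts[label] += 1
        rows.append([counts[label_] / i for label_ in labels])
    return labels, rows


def write_avatar_trace(result: AvatarResult, path) -> None:
    labels, rows = avatar_convergence(result)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["runIndex"] + labels)
        for i, row in enumerate(rows, start=1):
            writer.writerow([i] + [f"{x:.12g}" for x in row])


# ---------------------------------------------------------------------------
# Plots (best effort)


def render_firefront_plot(trace: Sequence[TraceRow], prefix) -> list[str]:
    """Set-size and set-mass panels; returns the files written.

    Degrades gracefully to no output when no plotting backend is
    available.
    """
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return []
    iters = [r.iteration for r in trace]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].plot(iters, [r.size_f for r in trace], label="|F|")
    axes[0].plot(iters, [r.size_n for r in trace], label="|N|")
    axes[0].plot(iters, [r.size_a for r in trace], label="|A|")
    axes[0].set_xlabel("expansion")
    axes[0].set_ylabel("states")
    axes[0].legend()
    axes[1].plot(iters, [r.mass_f for r in trace], label="mass(F)")
    axes[1].plot(iters, [r.mass_n for r in trace], label="mass(N)")
    axes[1].plot(iters, [r.mass_a for r in trace], label="mass(A)")
    axes[1].set_xlabel("expansion")
    axes[1].set_ylabel("probability")
    axes[1].legend()
    fig.tight_layout()
    out = f"{prefix}_firefront.png"
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return [out]


def render_avatar_plot(result: AvatarResult, prefix) -> list[str]:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return []
    labels, rows = avatar_convergence(result)
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = range(1, len(rows) + 1)
    for j, label in enumerate(labels):
        ax.plot(xs, [row[j] for row in rows], label=label)
    ax.set_xlabel("simulation")
    ax.set_ylabel("running estimate")
    ax.legend()
    fig.tight_layout()
    out = f"{prefix}_avatar.png"
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return [out]
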