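"""Reading and writing models, oracles and state strings.

The package's native model document is JSON::

    {"components": [{"name": "g0", "max": 1, "input": false}, ...],
     "regulators": {"g0": ["g1", "g2"], ...},
     "functions":  {"g0": {"table": [{"in": [0, 0], "out": 1}, ...]}, ...}}

Truth-table rows list the regulator levels in regulator order; every row of
the component's table must be present exactly once.  A tab-separated dialect
holds one block per component (blocks separated by blank lines), whose
header row names the regulators followed by the target component.

An oracle document is a JSON list of known attractors, each with a name and
either level-pattern strings (one character per component, a digit or ``*``)
or explicit integer state keys for explicit-graph dynamics.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .model import Component, LogicalModel, StateKey


class ModelFormatError(ValueError):
    """A model document violates the schema; the message names the spot."""


# ---------------------------------------------------------------------------
# JSON model format


def model_to_dict(model: LogicalModel) -> dict:
    doc: dict = {
        "components": [
            {"name": c.name, "max": c.max_level, "input": c.is_input}
            for c in model.components
        ],
        "regulators": {},
        "functions": {},
    }
    for i, comp in enumerate(model.components):
        regs = model.regulators[i]
        doc["regulators"][comp.name] = [model.components[r].name for r in regs]
        sizes = [model.components[r].max_level + 1 for r in regs]
        rows = []
        for idx, combo in enumerate(_mixed_radix_tuples(sizes)):
            rows.append({"in": list(combo), "out": int(model.tables[i][idx])})
        doc["functions"][comp.name] = {"table": rows}
    return doc


def _mixed_radix_tuples(sizes: Sequence[int]):
    """All level combinations in little-endian mixed-radix index order."""
    if not sizes:
        yield ()
        return
    # little-endian: the first regulator varies fastest
    for combo in itertools.product(*(range(s) for s in reversed(sizes))):
        yield tuple(reversed(combo))


def model_from_dict(doc: Mapping) -> LogicalModel:
    try:
        comp_docs = doc["components"]
        reg_doc = doc["regulators"]
        fun_doc = doc["functions"]
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"missing top-level section: {exc}") from None

    components = []
    for j, c in enumerate(comp_docs):
        try:
            components.append(
                Component(
                    str(c["name"]),
                    int(c.get("max", 1)),
                    bool(c.get("input", False)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelFormatError(f"components[{j}]: {exc}") from None
    index = {c.name: i for i, c in enumerate(components)}
    if len(index) != len(components):
        raise ModelFormatError("duplicate component name")

    regulators = []
    tables = []
    for i, comp in enumerate(components):
        if comp.name not in reg_doc:
            raise ModelFormatError(
                f"component {comp.name!r}: missing regulator list"
            )
        regs = []
        for rname in reg_doc[comp.name]:
            if rname not in index:
                raise ModelFormatError(
                    f"component {comp.name!r}: dangling regulator "
                    f"reference {rname!r}"
                )
            regs.append(index[rname])
        regulators.append(tuple(regs))

        if comp.name not in fun_doc:
            raise ModelFormatError(
                f"component {comp.name!r}: missing function"
            )
        rows = fun_doc[comp.name].get("table")
        if rows is None:
            raise ModelFormatError(
                f"component {comp.name!r}: function has no truth table"
            )
        sizes = [components[r].max_level + 1 for r in regs]
        expected = int(np.prod(sizes)) if regs else 1
        table = np.full(expected, -1, dtype=np.int64)
        places = np.concatenate(
            ([1], np.cumprod(np.array(sizes[:-1], dtype=np.int64)))
        ) if regs else np.array([], dtype=np.int64)
        for row in rows:
            combo = row.get("in")
            out = row.get("out")
            if combo is None or out is None:
                raise ModelFormatError(
                    f"component {comp.name!r}: table row missing 'in'/'out'"
                )
            if len(combo) != len(regs):
                raise ModelFormatError(
                    f"component {comp.name!r}: table row {combo} has "
                    f"{len(combo)} levels, expected {len(regs)}"
                )
            idx = 0
            for lvl, size, p in zip(combo, sizes, places):
                if not 0 <= int(lvl) < size:
                    raise ModelFormatError(
                        f"component {comp.name!r}: regulator level {lvl} "
                        "outside domain in table row"
                    )
                idx += int(lvl) * int(p)
            if not 0 <= int(out) <= comp.max_level:
                raise ModelFormatError(
                    f"component {comp.name!r}: target level {out} outside "
                    f"domain 0..{comp.max_level}"
                )
            if table[idx] != -1:
                raise ModelFormatError(
                    f"component {comp.name!r}: duplicate table row {combo}"
                )
            table[idx] = int(out)
        if (table == -1).any():
            missing = int(np.argmax(table == -1))
            raise ModelFormatError(
                f"component {comp.name!r}: missing truth-table row "
                f"(index {missing})"
            )
        tables.append(table)

    try:
        return LogicalModel(components, regulators, tables)
    except ValueError as exc:
        raise ModelFormatError(str(exc)) from None


def save_model(model: LogicalModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path) -> LogicalModel:
    text = Path(path).read_text()
    if text.lstrip().startswith("{"):
        return model_from_dict(json.loads(text))
    return model_from_tsv(text)


# ---------------------------------------------------------------------------
# Tab-separated truth-table dialect


def model_to_tsv(model: LogicalModel) -> str:
    blocks = []
    for i, comp in enumerate(model.components):
        regs = model.regulators[i]
        header = [model.components[r].name for r in regs] + [comp.name]
        lines = ["\t".join(header)]
        sizes = [model.components[r].max_level + 1 for r in regs]
        for idx, combo in enumerate(_mixed_radix_tuples(sizes)):
            lines.append(
                "\t".join(
                    [str(v) for v in combo] + [str(int(model.tables[i][idx]))]
                )
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def model_from_tsv(text: str) -> LogicalModel:
    """Parse the tab-separated dialect (see module docstring).

    Component domains are inferred from the levels appearing in the tables;
    a component whose sole regulator is itself with the identity function is
    recorded as an input.
    """
    blocks = [b for b in text.strip().split("\n\n") if b.strip()]
    if not blocks:
        raise ModelFormatError("empty truth-table document")

    parsed = []  # (target name, regulator names, rows)
    max_level: dict[str, int] = {}
    for b, block in enumerate(blocks):
        lines = [ln for ln in block.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if len(header) < 1:
            raise ModelFormatError(f"block {b}: empty header")
        *reg_names, target = header
        rows = []
        for ln in lines[1:]:
            cells = ln.split("\t")
            if len(cells) != len(header):
                raise ModelFormatError(
                    f"component {target!r}: row {ln!r} has {len(cells)} "
                    f"columns, expected {len(header)}"
                )
            combo = tuple(int(c) for c in cells[:-1])
            out = int(cells[-1])
            rows.append((combo, out))
            for name, lvl in zip(reg_names, combo):
                max_level[name] = max(max_level.get(name, 1), lvl)
            max_level[target] = max(max_level.get(target, 1), out)
        parsed.append((target, reg_names, rows))

    order = [target for target, _, _ in parsed]
    if len(set(order)) != len(order):
        raise ModelFormatError("duplicate component block")
    for target, reg_names, _ in parsed:
        for r in reg_names:
            if r not in order:
                raise ModelFormatError(
                    f"component {target!r}: dangling regulator reference {r!r}"
                )

    doc = {
        "components": [],
        "regulators": {},
        "functions": {},
    }
    for target, reg_names, rows in parsed:
        is_input = (
            reg_names == [target]
            and all(combo == (out,) for combo, out in rows)
        )
        doc["components"].append(
            {"name": target, "max": max_level[target], "input": is_input}
        )
        doc["regulators"][target] = list(reg_names)
        doc["functions"][target] = {
            "table": [{"in": list(c), "out": o} for c, o in rows]
        }
    return model_from_dict(doc)


# ---------------------------------------------------------------------------
# Oracles and state strings


@dataclass
class OracleAttractor:
    name: str
    patterns: tuple[str, ...] = ()
    keys: frozenset[int] = frozenset()


@dataclass
class Oracle:
    """User-supplied descriptions of known attractors.

    ``identify(state)`` returns the attractor name if the state matches a
    pattern (or explicit key), letting an exploration halt as soon as it
    enters a known attractor.
    """

    attractors: list[OracleAttractor]
    model: LogicalModel | None = None
    _key_index: dict[int, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for att in self.attractors:
            for key in att.keys:
                self._key_index[int(key)] = att.name
            if att.patterns and self.model is None:
                raise ValueError(
                    "pattern-based oracle requires a model to decode states"
                )
            for pat in att.patterns:
                if self.model and len(pat) != self.model.n:
                    raise ValueError(
                        f"oracle {att.name!r}: pattern {pat!r} length does "
                        f"not match the model"
                    )

    def identify(self, state: StateKey) -> str | None:
        hit = self._key_index.get(state)
        if hit is not None:
            return hit
        if self.model is None:
            return None
        levels = None
        for att in self.attractors:
            for pat in att.patterns:
                if levels is None:
                    levels = self.model.decode(state)
                if all(
                    ch == "*" or int(ch) == lvl
                    for ch, lvl in zip(pat, levels)
                ):
                    return att.name
        return None


def load_oracle(path, model: LogicalModel | None = None) -> Oracle:
    doc = json.loads(Path(path).read_text())
    attractors = []
    for entry in doc:
        attractors.append(
            OracleAttractor(
                name=str(entry["name"]),
                patterns=tuple(entry.get("states", ())),
                keys=frozenset(int(k) for k in entry.get("keys", ())),
            )
        )
    return Oracle(attractors, model=model)
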