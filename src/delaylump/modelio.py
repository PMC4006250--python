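"""Model configuration and tabular output files.

Models are stored as YAML with keys ``species`` (ordered list; declaration
order is the chain order), ``reactions`` (list of mappings with
``reactants``/``products`` as name -> stoichiometry maps and a ``rate``),
``sois`` and ``initial_state``.  Reaction ``kind`` is optional; the
classifier infers it and errors on contradiction.

Abridged models use the same format plus a ``delay`` block per delayed
reaction holding a closed-form descriptor (``stage_rates`` or ``residue``
terms) or an inline tabulated CDF.  Trajectories, ensemble summaries and
distributions are written as TSV.
"""

from __future__ import annotations

import numpy as np
import yaml

from .abridge import AbridgedModel, DelayedReaction
from .network import NetworkError, Reaction, ReactionKind, ReactionNetwork, Species
from .passage import (DelayDistribution, ResidueForm, StageConvolution,
                      TabulatedDistribution)
from .simulate import EnsembleResult, Trajectory

__all__ = ["read_model", "write_model", "read_abridged", "write_trajectory",
           "write_distribution", "write_ensemble_summary", "load_distribution"]


def _stoich_map(value, where: str) -> list[tuple[str, int]]:
    if value is None:
        return []
    if isinstance(value, dict):
        return [(str(k), int(v)) for k, v in value.items()]
    raise NetworkError(f"{where}: expected a species->stoichiometry mapping, got {value!r}")


def _reaction_from_dict(d: dict, i: int) -> Reaction:
    if "rate" not in d:
        raise NetworkError(f"reactions[{i}]: missing required key 'rate'")
    kind = None
    if "kind" in d and d["kind"] is not None:
        try:
            kind = ReactionKind(d["kind"])
        except ValueError as exc:
            raise NetworkError(f"reactions[{i}]: unknown kind {d['kind']!r}") from exc
    propensity = None
    if d.get("propensity") is not None:
        p = d["propensity"]
        propensity = (p["law"], {k: v for k, v in p.items() if k != "law"})
    return Reaction(
        reactants=_stoich_map(d.get("reactants"), f"reactions[{i}].reactants"),
        products=_stoich_map(d.get("products"), f"reactions[{i}].products"),
        rate_constant=float(d["rate"]),
        kind=kind,
        propensity=propensity,
    )


def read_model(path) -> ReactionNetwork:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise NetworkError(f"{path}: not a mapping at top level")
    for key in ("species", "reactions"):
        if key not in doc:
            raise NetworkError(f"{path}: missing required key '{key}'")
    species = [Species(str(nm), i + 1) for i, nm in enumerate(doc["species"])]
    reactions = [_reaction_from_dict(d, i) for i, d in enumerate(doc["reactions"])]
    return ReactionNetwork(
        species=species, reactions=reactions,
        sois=[str(s) for s in doc.get("sois", [])],
        initial_state={str(k): int(v) for k, v in (doc.get("initial_state") or {}).items()},
    )


def _reaction_to_dict(r: Reaction) -> dict:
    d: dict = {
        "reactants": {sp: st for sp, st in r.reactants},
        "products": {sp: st for sp, st in r.products},
        "rate": float(r.rate_constant),
    }
    if r.kind is not None:
        d["kind"] = r.kind.value
    if r.propensity is not None:
        law, params = r.propensity
        d["propensity"] = {"law": law, **params}
    return d


def _delay_to_dict(delay: DelayDistribution) -> dict:
    if isinstance(delay, StageConvolution):
        return {"stage_rates": [float(v) for v in delay.stage_rates]}
    if isinstance(delay, ResidueForm):
        return {"residue": {
            "eigenvalues": [[float(z.real), float(z.imag)] for z in delay.eigenvalues],
            "coefficients": [[float(z.real), float(z.imag)] for z in delay.coefficients],
        }}
    if isinstance(delay, TabulatedDistribution):
        step = max(1, delay.grid.size // 256)
        return {"tabulated": {
            "grid": [float(v) for v in delay.grid[::step]] + [float(delay.grid[-1])],
            "cdf": [float(v) for v in delay.cdf_values[::step]] + [float(delay.cdf_values[-1])],
        }}
    raise NetworkError(f"cannot serialize delay of type {type(delay).__name__}")


def load_distribution(d: dict) -> DelayDistribution:
    if "stage_rates" in d:
        return StageConvolution(d["stage_rates"])
    if "residue" in d:
        r = d["residue"]
        return ResidueForm([complex(a, b) for a, b in r["eigenvalues"]],
                           [complex(a, b) for a, b in r["coefficients"]])
    if "tabulated" in d:
        return TabulatedDistribution(d["tabulated"]["grid"], d["tabulated"]["cdf"])
    raise NetworkError(f"unknown delay descriptor with keys {sorted(d)}")


def write_model(model: ReactionNetwork | AbridgedModel, path) -> None:
    if isinstance(model, AbridgedModel):
        doc = {
            "species": model.species_names,
            "sois": list(model.sois),
            "reactions": [_reaction_to_dict(r) for r in model.immediate_reactions] + [
                {**_reaction_to_dict(r.reaction_view()),
                 "label": r.label, "delay": _delay_to_dict(r.delay)}
                for r in model.delayed_reactions
            ],
            "initial_state": dict(model.initial_state),
        }
    else:
        doc = {
            "species": model.species_names,
            "sois": list(model.sois),
            "reactions": [_reaction_to_dict(r) for r in model.reactions],
            "initial_state": dict(model.initial_state),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_abridged(path) -> AbridgedModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    species = [Species(str(nm), i + 1) for i, nm in enumerate(doc["species"])]
    immediate, delayed = [], []
    for i, d in enumerate(doc["reactions"]):
        r = _reaction_from_dict(d, i)
        if "delay" in d:
            delayed.append(DelayedReaction(
                reactants=r.reactants, products=r.products,
                rate_constant=r.rate_constant,
                delay=load_distribution(d["delay"]),
                label=d.get("label", "first_arrival"),
                propensity=r.propensity,
            ))
        else:
            immediate.append(r)
    return AbridgedModel(
        species=species, sois=[str(s) for s in doc.get("sois", [])],
        delayed_reactions=delayed, immediate_reactions=immediate,
        initial_state={str(k): int(v) for k, v in (doc.get("initial_state") or {}).items()},
        synthesis_attached=True,
    )


def write_trajectory(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("time\t" + "\t".join(traj.species) + "\n")
        for t, row in zip(traj.times, traj.states):
            fh.write(f"{t:.10g}\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_ensemble_summary(ens: EnsembleResult, path) -> None:
    mean = ens.counts.mean(axis=0)
    var = ens.counts.var(axis=0, ddof=1)
    with open(path, "w") as fh:
        cols = [f"mean_{s}" for s in ens.species] + [f"var_{s}" for s in ens.species]
        fh.write("time\t" + "\t".join(cols) + f"\t# runs={ens.n_runs}\n")
        for g, t in enumerate(ens.grid):
            vals = [f"{v:.8g}" for v in mean[g]] + [f"{v:.8g}" for v in var[g]]
            fh.write(f"{t:.10g}\t" + "\t".join(vals) + "\n")


def write_distribution(d: DelayDistribution, path, name: str = "delay",
                       grid=None) -> None:
    """Two-column TSV (time, CDF) with a header comment naming the
    distribution."""
    if grid is None:
        if isinstance(d, TabulatedDistribution):
            grid = d.grid
        else:
            top = d.quantile(1.0 - 1e-9)
            grid = np.concatenate([[0.0], np.geomspace(top * 1e-4, top, 511)])
    vals = np.asarray(d.cdf(np.asarray(grid, dtype=float)))
    with open(path, "w") as fh:
        fh.write(f"# distribution: {name}\n")
        fh.write("time\tcdf\n")
        for t, v in zip(grid, vals):
            fh.write(f"{t:.10g}\t{v:.12g}\n")
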