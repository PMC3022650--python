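"""Model I/O in the package dialect.

Two on-disk forms carry the same fields:

* one JSON document with ``metabolites``, ``reactions``, ``biomass_reaction``
  and ``atpm_reaction``;
* a pair of TSV tables (``<stem>.metabolites.tsv`` + ``<stem>.reactions.tsv``)
  with stoichiometry serialized as comma-separated ``met_id:coeff`` pairs.

Writing is canonical (sorted records, shortest-repr floats), so
``load_model(write_model(m))`` round-trips bit-identically on canonical files.
"""

from __future__ import annotations

import json
from pathlib import Path

from .model import Metabolite, Model, Reaction, validate_model


class ModelParseError(ValueError):
    """Raised on malformed model files, with record context."""


def shipped_model_path(species: str) -> Path:
    """Path of a core-model fixture shipped with the package (pcar | ppro)."""
    path = Path(__file__).parent / "data" / f"{species}_core.json"
    if not path.exists():
        raise FileNotFoundError(path)
    return path


def _met_to_dict(m: Metabolite) -> dict:
    d = {"id": m.id, "name": m.name, "compartment": m.compartment}
    if m.formula is not None:
        d["formula"] = m.formula
    if m.charge is not None:
        d["charge"] = m.charge
    return d


def _rxn_to_dict(r: Reaction) -> dict:
    return {
        "id": r.id,
        "name": r.name,
        "stoichiometry": {k: float(r.stoichiometry[k]) for k in sorted(r.stoichiometry)},
        "lower_bound": r.lower_bound,
        "upper_bound": r.upper_bound,
        "gpr": r.gpr,
        "subsystem": r.subsystem,
    }


def model_to_dict(model: Model) -> dict:
    return {
        "id": model.id,
        "species": model.species,
        "biomass_reaction": model.biomass_reaction_id,
        "atpm_reaction": model.atpm_reaction_id,
        "metabolites": sorted((_met_to_dict(m) for m in model.metabolites), key=lambda d: d["id"]),
        "reactions": sorted((_rxn_to_dict(r) for r in model.reactions), key=lambda d: d["id"]),
        "annotations": {k: model.annotations[k] for k in sorted(model.annotations)},
    }


def model_from_dict(doc: dict) -> Model:
    try:
        mets = [
            Metabolite(
                id=d["id"],
                name=d.get("name", ""),
                compartment=d.get("compartment", "c"),
                formula=d.get("formula"),
                charge=d.get("charge"),
            )
            for d in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                id=d["id"],
                name=d.get("name", ""),
                stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
                lower_bound=float(d["lower_bound"]),
                upper_bound=float(d["upper_bound"]),
                gpr=d.get("gpr", ""),
                subsystem=d.get("subsystem", "Other"),
            )
            for d in doc["reactions"]
        ]
        return Model(
            id=doc.get("id", "model"),
            species=doc.get("species", ""),
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id=doc["biomass_reaction"],
            atpm_reaction_id=doc["atpm_reaction"],
            annotations=doc.get("annotations", {}),
        )
    except KeyError as exc:
        raise ModelParseError(f"missing required field {exc.args[0]!r}") from exc


def _check(model: Model, path) -> Model:
    hard = [
        v
        for v in validate_model(model)
        if v.code
        in ("duplicate-metabolite", "duplicate-reaction", "unknown-compartment", "missing-metabolite")
    ]
    if hard:
        raise ModelParseError(f"{path}: " + "; ".join(str(v) for v in hard))
    return model


def _stoich_to_str(st: dict[str, float]) -> str:
    return ",".join(f"{k}:{repr(float(st[k]))}" for k in sorted(st))


def _stoich_from_str(s: str, context: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for pair in s.split(","):
        pair = pair.strip()
        if not pair:
            continue
        try:
            mid, coeff = pair.rsplit(":", 1)
            out[mid.strip()] = float(coeff)
        except ValueError as exc:
            raise ModelParseError(f"{context}: bad stoichiometry entry {pair!r}") from exc
    return out


def load_model(path: str | Path) -> Model:
    """Load a model from the JSON dialect or a TSV table pair."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
        return _check(model_from_dict(doc), path)
    if path.name.endswith(".reactions.tsv") or path.name.endswith(".metabolites.tsv"):
        stem = str(path)
        for suffix in (".reactions.tsv", ".metabolites.tsv"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        return _load_tsv(Path(stem))
    raise ModelParseError(f"{path}: unrecognized model file extension")


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ModelParseError(f"{path}: empty table")
    header = lines[0].split("\t")
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ModelParseError(f"{path}: line {i}: expected {len(header)} columns")
        rows.append(dict(zip(header, cells)))
    return rows


def _load_tsv(stem: Path) -> Model:
    mpath = Path(str(stem) + ".metabolites.tsv")
    rpath = Path(str(stem) + ".reactions.tsv")
    mets = []
    header_meta: dict[str, str] = {}
    for row in _read_tsv(mpath):
        if row["id"].startswith("#"):
            header_meta[row["id"].lstrip("#")] = row["name"]
            continue
        mets.append(
            Metabolite(
                id=row["id"],
                name=row["name"],
                compartment=row["compartment"],
                formula=row["formula"] or None,
                charge=int(row["charge"]) if row["charge"] else None,
            )
        )
    rxns = []
    for row in _read_tsv(rpath):
        if row["id"].startswith("#"):
            header_meta[row["id"].lstrip("#")] = row["name"]
            continue
        rxns.append(
            Reaction(
                id=row["id"],
                name=row["name"],
                stoichiometry=_stoich_from_str(
                    row["stoichiometry"], f"{rpath}: reaction {row['id']!r}"
                ),
                lower_bound=float(row["lower_bound"]),
                upper_bound=float(row["upper_bound"]),
                gpr=row["gpr"],
                subsystem=row["subsystem"],
            )
        )
    for key in ("model_id", "species", "biomass_reaction", "atpm_reaction"):
        if key not in header_meta:
            raise ModelParseError(f"{mpath}/{rpath}: missing #{key} header row")
    return _check(
        Model(
            id=header_meta["model_id"],
            species=header_meta["species"],
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id=header_meta["biomass_reaction"],
            atpm_reaction_id=header_meta["atpm_reaction"],
        ),
        stem,
    )


def write_model(model: Model, path: str | Path) -> Path:
    """Write a model canonically; format chosen from the path name."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = model_to_dict(model)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return path
    # TSV pair; `path` is the stem
    stem = str(path)
    for suffix in (".reactions.tsv", ".metabolites.tsv", ".tsv"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    meta_rows = [
        ("#model_id", model.id),
        ("#species", model.species),
        ("#biomass_reaction", model.biomass_reaction_id),
        ("#atpm_reaction", model.atpm_reaction_id),
    ]
    with open(stem + ".metabolites.tsv", "w") as fh:
        fh.write("id\tname\tcompartment\tformula\tcharge\n")
        for key, val in meta_rows:
            fh.write(f"{key}\t{val}\t\t\t\n")
        for m in sorted(model.metabolites, key=lambda m: m.id):
            fh.write(
                f"{m.id}\t{m.name}\t{m.compartment}\t{m.formula or ''}\t"
                f"{'' if m.charge is None else m.charge}\n"
            )
    with open(stem + ".reactions.tsv", "w") as fh:
        fh.write("id\tname\tstoichiometry\tlower_bound\tupper_bound\tgpr\tsubsystem\n")
        for r in sorted(model.reactions, key=lambda r: r.id):
            fh.write(
                f"{r.id}\t{r.name}\t{_stoich_to_str(r.stoichiometry)}\t"
                f"{repr(r.lower_bound)}\t{repr(r.upper_bound)}\t{r.gpr}\t{r.subsystem}\n"
            )
    return Path(stem + ".reactions.tsv")
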