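"""Three-population demographic scenarios and the 20-model catalog.

Each scenario describes, backward in time, the history of three extant
genetic clusters (East, West1, West2): population sizes, divergence or
admixture events, and per-epoch migration.  Sizes are diploid effective
sizes, times are generations, and migration parameters are backward
per-generation lineage-movement probabilities (the coalescent-simulator
convention: ``M_ab`` moves lineages from ``a`` into ``b`` as time runs
backward).

The catalog spans the model families compared in the analysis: nine
two-divergence models (three topologies x three gene-flow variants),
nine admixture-origin models (each extant cluster in turn created by
admixture between the other two, x three gene-flow variants), and two
trifurcation models.  Model 1 — East diverging first, then West1/West2,
with recent and historical bidirectional gene flow — ships
pre-parameterised with the published point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .datasets import MODEL1_ESTIMATES

EXTANT = ("East", "West1", "West2")

#: default search bounds by parameter kind (log-uniform draws)
DEFAULT_BOUNDS = {
    "size": (1e3, 5e6),
    "time": (1e3, 5e6),
    "migration": (1e-9, 1e-3),
    "proportion": (0.05, 0.95),
}


@dataclass
class Parameter:
    name: str
    value: float | None
    bounds: tuple
    log: bool = True
    fixed: bool = False


class ScenarioError(ValueError):
    """Scenario parameters violate their structural constraints."""


@dataclass
class DemographicScenario:
    """Declarative backward-in-time model for three sampled clusters.

    ``sizes`` maps every population label (extant and ancestral) to a
    parameter name; ``events`` is an ordered list of dicts of type
    ``split`` (derived populations merge into an ancestral one) or
    ``admixture`` (a derived population's lineages move into two
    ancestral sources); ``migrations`` lists backward lineage-movement
    entries with a ``start`` (0 or a time-parameter name) and optional
    explicit ``end``.  ``time_orderings`` lists (earlier, later) pairs of
    time-parameter names enforced during validation and search.
    """

    name: str
    populations: tuple = EXTANT
    sizes: dict = field(default_factory=dict)
    events: list = field(default_factory=list)
    migrations: list = field(default_factory=list)
    params: dict = field(default_factory=dict)
    time_orderings: list = field(default_factory=list)

    # -- parameters ------------------------------------------------------
    def free_params(self) -> list:
        return [p.name for p in self.params.values() if not p.fixed]

    @property
    def k(self) -> int:
        return len(self.free_params())

    def values(self, overrides: dict | None = None) -> dict:
        out = {n: p.value for n, p in self.params.items()}
        if overrides:
            unknown = set(overrides) - set(out)
            if unknown:
                raise ScenarioError(f"unknown parameters {sorted(unknown)}")
            out.update(overrides)
        return out

    def with_values(self, values: dict) -> "DemographicScenario":
        params = {
            n: replace(p, value=values.get(n, p.value))
            for n, p in self.params.items()
        }
        return replace(self, params=params)

    # -- validation ------------------------------------------------------
    def validate(self, overrides: dict | None = None) -> dict:
        v = self.values(overrides)
        missing = [n for n, val in v.items() if val is None]
        if missing:
            raise ScenarioError(f"parameters without values: {missing}")
        for label, pname in self.sizes.items():
            if v[pname] <= 0:
                raise ScenarioError(f"non-positive size {pname} for {label}")
        for ev in self.events:
            if v[ev["time"]] <= 0:
                raise ScenarioError(f"non-positive time {ev['time']}")
            if ev["type"] == "admixture":
                a = v[ev["proportion"]]
                if not 0 < a < 1:
                    raise ScenarioError(
                        f"admixture proportion {ev['proportion']} not in (0,1)")
        for mig in self.migrations:
            if v[mig["rate"]] < 0:
                raise ScenarioError(f"negative migration {mig['rate']}")
        for earlier, later in self.time_orderings:
            if not v[earlier] < v[later]:
                raise ScenarioError(
                    f"time ordering violated: {earlier} >= {later}")
        return v

    # -- msprime ---------------------------------------------------------
    def to_demography(self, overrides: dict | None = None):
        import msprime

        v = self.validate(overrides)
        dem = msprime.Demography()
        extant = set(self.populations)
        for label, pname in self.sizes.items():
            dem.add_population(
                name=label, initial_size=v[pname],
                initially_active=label in extant)
        for mig in self.migrations:
            if mig.get("start", 0) == 0:
                dem.set_migration_rate(
                    source=mig["source"], dest=mig["dest"],
                    rate=v[mig["rate"]])
        timed = []
        for ev in self.events:
            timed.append((v[ev["time"]], 0, ("event", ev)))
        for mig in self.migrations:
            start = mig.get("start", 0)
            if start != 0:
                timed.append((v[start], 1, ("mig_on", mig)))
            end = mig.get("end")
            if end is not None:
                timed.append((v[end], 1, ("mig_off", mig)))
        # same-time ties: structural events first, then rate changes
        for _, _, (kind, obj) in sorted(timed, key=lambda t: (t[0], t[1])):
            if kind == "event":
                if obj["type"] == "split":
                    dem.add_population_split(
                        time=v[obj["time"]], derived=list(obj["derived"]),
                        ancestral=obj["ancestral"])
                elif obj["type"] == "admixture":
                    a = v[obj["proportion"]]
                    dem.add_admixture(
                        time=v[obj["time"]], derived=obj["derived"],
                        ancestral=list(obj["ancestral"]),
                        proportions=[a, 1.0 - a])
                else:
                    raise ScenarioError(f"unknown event type {obj['type']!r}")
            elif kind == "mig_on":
                dem.add_migration_rate_change(
                    time=v[obj["start"]], source=obj["source"],
                    dest=obj["dest"], rate=v[obj["rate"]])
            else:
                dem.add_migration_rate_change(
                    time=v[obj["end"]], source=obj["source"],
                    dest=obj["dest"], rate=0.0)
        dem.sort_events()
        return dem


# ---------------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------------

def _param(name: str, kind: str, value: float | None = None,
           fixed: bool = False) -> Parameter:
    return Parameter(name, value, DEFAULT_BOUNDS[kind],
                     log=kind != "proportion", fixed=fixed)


def _recent_migrations(pairs) -> list:
    return [{"source": a, "dest": b, "rate": f"M_{a}_{b}", "start": 0}
            for a, b in pairs]


def _all_recent_pairs() -> list:
    return [(a, b) for a in EXTANT for b in EXTANT if a != b]


def two_divergence_scenario(first_off: str, flow: str,
                            name: str) -> DemographicScenario:
    """Two divergence events: ``first_off`` splits from the ancestor of
    the remaining pair.  ``flow``: none / recent / full (recent +
    historical)."""
    pair = tuple(p for p in EXTANT if p != first_off)
    sizes = {p: f"N_cur_{p}" for p in EXTANT}
    sizes["AncPair"] = "N_Anc_pair"
    sizes["AncAll"] = "N_Anc_all"
    events = [
        {"type": "split", "time": "T_2", "derived": list(pair),
         "ancestral": "AncPair"},
        {"type": "split", "time": "T_1", "derived": [first_off, "AncPair"],
         "ancestral": "AncAll"},
    ]
    migrations: list = []
    params = {f"N_cur_{p}": _param(f"N_cur_{p}", "size") for p in EXTANT}
    params["N_Anc_pair"] = _param("N_Anc_pair", "size")
    params["N_Anc_all"] = _param("N_Anc_all", "size")
    params["T_1"] = _param("T_1", "time")
    params["T_2"] = _param("T_2", "time")
    if flow in ("recent", "full"):
        migrations += _recent_migrations(_all_recent_pairs())
        for m in migrations:
            params[m["rate"]] = _param(m["rate"], "migration")
    if flow == "full":
        for a, b in ((first_off, "AncPair"), ("AncPair", first_off)):
            rate = f"M_{a}_{b}"
            migrations.append({"source": a, "dest": b, "rate": rate,
                               "start": "T_2"})
            params[rate] = _param(rate, "migration")
    return DemographicScenario(
        name=name, sizes=sizes, events=events, migrations=migrations,
        params=params, time_orderings=[("T_2", "T_1")])


def admixture_scenario(admixed: str, flow: str, name: str
                       ) -> DemographicScenario:
    """``admixed`` is created at T_adm by admixture of the other two
    clusters, which themselves diverged at T_1."""
    sources = tuple(p for p in EXTANT if p != admixed)
    sizes = {p: f"N_cur_{p}" for p in EXTANT}
    sizes["AncAll"] = "N_Anc_all"
    events = [
        {"type": "admixture", "time": "T_adm", "derived": admixed,
         "ancestral": list(sources), "proportion": "alpha"},
        {"type": "split", "time": "T_1", "derived": list(sources),
         "ancestral": "AncAll"},
    ]
    params = {f"N_cur_{p}": _param(f"N_cur_{p}", "size") for p in EXTANT}
    params["N_Anc_all"] = _param("N_Anc_all", "size")
    params["T_1"] = _param("T_1", "time")
    params["T_adm"] = _param("T_adm", "time")
    params["alpha"] = _param("alpha", "proportion")
    migrations: list = []
    if flow in ("recent", "full"):
        migrations += _recent_migrations(_all_recent_pairs())
        for m in migrations:
            m["end"] = "T_adm"
            params[m["rate"]] = _param(m["rate"], "migration")
    if flow == "full":
        for a, b in (sources, sources[::-1]):
            rate = f"Mh_{a}_{b}"
            migrations.append({"source": a, "dest": b, "rate": rate,
                               "start": "T_adm"})
            params[rate] = _param(rate, "migration")
    return DemographicScenario(
        name=name, sizes=sizes, events=events, migrations=migrations,
        params=params, time_orderings=[("T_adm", "T_1")])


def trifurcation_scenario(flow: str, name: str) -> DemographicScenario:
    sizes = {p: f"N_cur_{p}" for p in EXTANT}
    sizes["AncAll"] = "N_Anc_all"
    events = [{"type": "split", "time": "T_1", "derived": list(EXTANT),
               "ancestral": "AncAll"}]
    params = {f"N_cur_{p}": _param(f"N_cur_{p}", "size") for p in EXTANT}
    params["N_Anc_all"] = _param("N_Anc_all", "size")
    params["T_1"] = _param("T_1", "time")
    migrations: list = []
    if flow == "recent":
        migrations += _recent_migrations(_all_recent_pairs())
        for m in migrations:
            params[m["rate"]] = _param(m["rate"], "migration")
    return DemographicScenario(
        name=name, sizes=sizes, events=events, migrations=migrations,
        params=params)


def model1_scenario() -> DemographicScenario:
    """The best-fit model, pre-parameterised with the published point
    estimates: East splits first (T_1), West1/West2 next (T_2), recent
    migration among all extant pairs and historical migration between
    East and the western ancestor."""
    sc = two_divergence_scenario("East", "full", "model01")
    est = MODEL1_ESTIMATES
    mapping = {
        "N_cur_East": est["N_cur_East"],
        "N_cur_West1": est["N_cur_W1"],
        "N_cur_West2": est["N_cur_W2"],
        "N_Anc_pair": est["N_Anc_w12"],
        "N_Anc_all": est["N_Anc_all"],
        "T_1": est["T_1"],
        "T_2": est["T_2"],
        "M_West1_West2": est["M12"],
        "M_West2_West1": est["M21"],
        "M_East_West1": est["M01"],
        "M_West1_East": est["M10"],
        "M_West2_East": est["M20"],
        "M_East_West2": est["M02"],
        "M_East_AncPair": est["M0_w12"],
        "M_AncPair_East": est["Mw12_0"],
    }
    return sc.with_values(mapping)


def rate_to_2nm(rate: float, ne: float) -> float:
    """Scaled migrant number 2Nm from a per-generation migration
    probability and the receiving deme's diploid Ne."""
    return 2.0 * ne * rate


def two_nm_to_rate(two_nm: float, ne: float) -> float:
    """Per-generation migration probability from a scaled 2Nm."""
    return two_nm / (2.0 * ne)


def panmictic_scenario(ne: float, name: str = "panmictic"
                       ) -> DemographicScenario:
    """A single constant-size population (neutral-expectation checks)."""
    return DemographicScenario(
        name=name, populations=("pop",), sizes={"pop": "N"},
        params={"N": _param("N", "size", value=ne, fixed=True)})


def island_scenario(ne: float, m: float, name: str = "island"
                    ) -> DemographicScenario:
    """Two demes of size ``ne`` exchanging migrants at backward rate ``m``."""
    params = {
        "N": _param("N", "size", value=ne, fixed=True),
        "m": _param("m", "migration", value=m, fixed=True),
    }
    migs = [{"source": a, "dest": b, "rate": "m", "start": 0}
            for a, b in (("d1", "d2"), ("d2", "d1"))]
    return DemographicScenario(
        name=name, populations=("d1", "d2"),
        sizes={"d1": "N", "d2": "N"}, migrations=migs, params=params)


def split_scenario(ne_a: float, ne_b: float, ne_anc: float, t_split: float,
                   name: str = "split", free=(), bounds: dict | None = None
                   ) -> DemographicScenario:
    """Two populations diverging from a common ancestor, no migration.

    ``free`` names parameters left free for fitting; ``bounds`` overrides
    their default search ranges.
    """
    params = {
        "N_a": _param("N_a", "size", value=ne_a),
        "N_b": _param("N_b", "size", value=ne_b),
        "N_anc": _param("N_anc", "size", value=ne_anc),
        "T": _param("T", "time", value=t_split),
    }
    for n, p in params.items():
        p.fixed = n not in free
        if bounds and n in bounds:
            p.bounds = bounds[n]
    return DemographicScenario(
        name=name, populations=("a", "b"),
        sizes={"a": "N_a", "b": "N_b", "Anc": "N_anc"},
        events=[{"type": "split", "time": "T", "derived": ["a", "b"],
                 "ancestral": "Anc"}],
        params=params)


def scenario_catalog() -> list:
    """The 20 compared demographic models.

    Models 1–9: two-divergence topologies (East, West1, West2 splitting
    first) x gene flow (full, recent, none); models 10–18:
    admixture-origin of each cluster x the same gene-flow variants;
    models 19–20: trifurcation without and with recent gene flow.
    Model 1 carries the published point estimates; all other parameter
    values are free.
    """
    catalog = []
    i = 1
    for first_off in EXTANT:
        for flow in ("full", "recent", "none"):
            if i == 1:
                catalog.append(model1_scenario())
            else:
                catalog.append(two_divergence_scenario(
                    first_off, flow, f"model{i:02d}"))
            i += 1
    for admixed in EXTANT:
        for flow in ("full", "recent", "none"):
            catalog.append(admixture_scenario(admixed, flow, f"model{i:02d}"))
            i += 1
    for flow in ("none", "recent"):
        catalog.append(trifurcation_scenario(flow, f"model{i:02d}"))
        i += 1
    return catalog
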