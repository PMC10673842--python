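"""Convert in-memory plate fixtures to serialisable experiment configs."""

from __future__ import annotations

from .fixtures import PlateFixture


def fixture_config_dict(fixture: PlateFixture, seed: int = 0) -> dict:
    """Config-file dictionary (validatable by load_config) for a fixture."""
    circuits: dict[str, dict] = {}
    circuit_names: dict[str, str] = {}
    protocols: dict[str, dict] = {}
    protocol_names: dict[tuple, str] = {}
    wells: dict[str, dict] = {}

    for w, circ in fixture.circuits.items():
        key = (circ.kind, circ.k_prod, circ.half_max_light, circ.hill_n,
               circ.switch_delay)
        name = circuit_names.get(repr(key))
        if name is None:
            name = f"{circ.kind}_{len(circuits)}"
            circuit_names[repr(key)] = name
            circuits[name] = {"kind": circ.kind, "k_prod": circ.k_prod,
                              "half_max_light": circ.half_max_light,
                              "hill_n": circ.hill_n,
                              "switch_delay": circ.switch_delay}
        prot = fixture.protocols[w]
        pkey = (prot.intensity, prot.t_on, prot.t_off, prot.active)
        pname = protocol_names.get(pkey)
        if pname is None:
            pname = f"protocol_{len(protocols)}"
            protocol_names[pkey] = pname
            protocols[pname] = {"intensity": prot.intensity,
                                "t_on": prot.t_on, "t_off": prot.t_off,
                                "active": prot.active}
        wells[w] = {"circuit": name, "protocol": pname,
                    "initial_turbidity": fixture.cultures[w].turbidity,
                    "inducer": w in fixture.inducer_wells}

    plan = fixture.plan
    return {
        "seed": seed,
        "twin": {"seed": seed},
        "circuits": circuits,
        "protocols": protocols,
        "wells": wells,
        "policies": [{"kind": p.kind, "threshold": p.threshold,
                      "wells": list(p.wells)} for p in fixture.policies],
        "plan": {"od_period_min": plan.od_period_min,
                 "fluor_period_min": plan.fluor_period_min,
                 "n_avg": plan.n_avg, "duration_h": plan.duration_h},
    }
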