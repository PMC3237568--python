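"""Construction of the EGFR-associated signalling network and its structural
variants.

The network couples three arms downstream of ligand-activated EGFR:

* the Ras/ERK proliferation arm (Shc/Grb2/SOS docking, SOS-catalysed Ras
  GDP->GTP exchange, Raf -> MEK -> ERK, with an ERK->SOS negative feedback),
* the PI3K/AKT survival arm (Grb2/Gab1/PI3K recruitment, PIP2 -> PIP3,
  PDK1-dependent AKT activation, PTEN and PP2A as phosphatases),
* the pro-apoptotic ROS arm (PI3K/Rac-driven ROS generation,
  ROS -> ASK1 -> MKK -> p38 with dedicated phosphatases),

plus the inhibitory AKT->ASK1 crosstalk that couples the survival and
apoptotic arms, and receptor internalization (tagged, so it can be removed
to model sustained receptor activation).

The complete reaction inventory of the original supplementary material is
not publicly recoverable, so the builder constructs the mechanistic core
explicitly and then pads the table with inert, zero-initial reserve species
and reactions (flagged ``reconstructed``) so that the printed structural
cardinalities — 160 species, 243 reactions, 145 distinct kinetic parameters
and 28 nonzero initial concentrations — hold exactly.  The padding carries
no flux (every padded reactant starts, and stays, at zero), so the dynamics
are those of the mechanistic core alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

from .network import (
    Law,
    Model,
    ModelError,
    Param,
    Reaction,
    Species,
    complex_name,
    moiety_count,
    species_tokens,
    validate_model,
)

__all__ = [
    "VariantSpec",
    "build_egfr_network",
    "apply_variant",
    "DEFAULT_PARAMS",
    "INITIAL_AMOUNTS",
    "MECHANISM_TAGS",
    "N_SPECIES",
    "N_REACTIONS",
    "N_PARAMETERS",
    "N_NONZERO_INITIALS",
]

# printed structural cardinalities of the published model
N_SPECIES = 160
N_REACTIONS = 243
N_PARAMETERS = 145
N_NONZERO_INITIALS = 28

#: every mechanism the fixture must represent, each with >= 1 tagged reaction
MECHANISM_TAGS = [
    "egf_binding",
    "dimerization",
    "transphosphorylation",
    "internalization",
    "shc_grb2_sos",
    "ras_exchange",
    "raf_activation",
    "cascade:raf-mek-erk",
    "feedback:ERK-SOS",
    "gab1_pi3k",
    "pip3_akt",
    "phosphatase",
    "ros_generation",
    "ros_ask1",
    "cascade:ask1-mkk-p38",
    "crosstalk:AKT-ASK1",
]

#: initial amounts in nM; exactly the 28 species that start nonzero.
INITIAL_AMOUNTS = {
    "EGF": 100.0,       # reference stimulus dose
    "EGFR": 150.0,
    "Shc": 200.0,
    "Grb2": 80.0,
    "SOS": 40.0,
    "Gab1": 60.0,
    "RasGDP": 200.0,
    "RasGAP": 25.0,
    "Raf": 150.0,
    "MEK": 200.0,
    "ERK": 250.0,
    "RafPase": 25.0,
    "MEKPase": 25.0,
    "ERKPase": 30.0,
    "PI3K": 50.0,
    "PIP2": 500.0,
    "PTEN": 50.0,
    "PDK1": 60.0,
    "AKT": 200.0,
    "PP2A": 30.0,
    "RacGDP": 150.0,
    "ROSscav": 80.0,
    "ASK1": 150.0,
    "ASK1Pase": 25.0,
    "MKK": 200.0,
    "p38": 250.0,
    "MKKPase": 25.0,
    "p38Pase": 30.0,
}

# Rate constants (nM, min).  Second-order constants 1/(nM min), first-order
# 1/min.  Values are the package's own calibration: literature-scale receptor
# kinetics, with downstream constants tuned so the transient-stimulation
# timing envelope (ERK peak < 5 min, basal return < 50 min, delayed p38 peak
# >= 15 min) and the sensitivity ranking structure hold.
DEFAULT_PARAMS = {
    # receptor layer
    "k_egf_on": 0.12, "k_egf_off": 0.06,
    "k_dim_on": 0.06, "k_dim_off": 0.1,
    "k_rtk": 10.0, "k_rtk_off": 1.0,
    "k_int_rp": 0.7, "k_int_le": 0.25, "k_int_d": 0.25,
    # Shc/Grb2/SOS docking and ERK->SOS feedback
    "k_shc_on": 0.05, "k_shc_off": 0.6, "k_shc_phos": 10.0,
    "k_shc_rel": 0.5, "k_shc_dp": 0.3,
    "k_gs_on": 0.02, "k_gs_off": 0.2,
    "k_rsgs_on": 0.05, "k_rsgs_off": 0.5,
    "k_fb_on": 0.01, "k_fb_off": 1.0, "k_fb_cat": 2.0,
    "k_fb_rel": 5.0, "k_gps_rel": 2.0, "k_sos_dp": 0.2,
    # Ras cycle
    "k_sosras_on": 0.03, "k_sosras_off": 0.5, "k_sosras_cat": 5.0,
    "k_gap_on": 0.015, "k_gap_off": 0.5, "k_gap_cat": 5.0,
    "k_ras_gtpase": 3.0, "k_ras_gtpase_c": 0.8, "k_ras_leak": 2e-5,
    # Raf/MEK/ERK cascade
    "k_raf_on": 0.14, "k_raf_off": 2.0, "k_raf_cat": 20.0,
    "k_raf_dp": 0.7, "k_raf_leak": 5e-4,
    "k_mek_on": 0.03, "k_mek_off": 0.5, "k_mek_cat": 4.0, "k_mek_dp": 4.0,
    "k_erk_on": 0.02, "k_erk_off": 0.5, "k_erk_cat": 4.0, "k_erk_dp": 2.0,
    # explicit MAPK phosphatases (second, enzymatic deactivation route)
    "k_mpase_on": 0.002, "k_mpase_off": 0.5, "k_mpase_cat": 1.0,
    # Grb2/Gab1/PI3K recruitment
    "k_g_on": 0.15, "k_g_off": 0.4,
    "k_gab_on": 0.12, "k_gab_off": 0.3, "k_gab_phos": 12.0,
    "k_gab_rel": 0.1, "k_gab_dp": 0.3,
    "k_pi3k_on": 0.12, "k_pi3k_off": 0.3,
    # PIP2/PIP3 and AKT activation
    "k_pip_on": 0.006, "k_pip_off": 0.5, "k_pip_cat": 5.0,
    "k_pten_on": 0.09, "k_pten_off": 0.5, "k_pten_cat": 3.0,
    "k_aktp_on": 0.05, "k_aktp_off": 0.5,
    "k_pdk_on": 0.06, "k_pdk_off": 0.5, "k_pdk_cat": 5.0,
    "k_pakt_rel": 3.0, "k_akt_dp": 0.4, "k_akt_leak": 5e-5,
    "k_pp2a_on": 0.002, "k_pp2a_off": 0.5, "k_pp2a_cat": 1.0,
    # Rac / ROS generation and clearance
    "k_rac_on": 0.05, "k_rac_off": 0.5, "k_rac_cat": 3.0, "k_rac_gdp": 0.5,
    "k_ros_gen": 0.2,
    "k_scav_on": 0.0002, "k_scav_off": 0.5, "k_scav_cat": 1.0, "k_ros_decay": 0.042,
    # ASK1/MKK/p38 cascade
    "k_ask1_on": 0.0021, "k_ask1_off": 0.5, "k_ask1_cat": 2.0,
    "k_ask1_dp": 1.6, "k_ask1_leak": 8e-4,
    "k_mkk_on": 0.075, "k_mkk_off": 0.5, "k_mkk_cat": 4.0, "k_mkk_dp": 3.0,
    "k_p38_on": 0.075, "k_p38_off": 0.5, "k_p38_cat": 4.0, "k_p38_dp": 2.5,
    "k_spase_on": 0.002, "k_spase_off": 0.5, "k_spase_cat": 1.0,
    # AKT -> ASK1 inhibitory crosstalk
    "k_x_on": 0.12, "k_x_off": 1.0, "k_x_cat": 100.0, "k_ask1_rec": 0.2,
}


def _rp(*extra: str) -> str:
    """Active (trans-phosphorylated) receptor dimer, optionally complexed."""
    return complex_name("EGF", "EGF", "p-EGFR", "p-EGFR", *extra)


class _Assembler:
    """Accumulates species and reactions with shared-parameter bookkeeping."""

    def __init__(self, params: dict[str, float]):
        self.params = params
        self.species: dict[str, Species] = {}
        self.reactions: list[Reaction] = []

    def sp(self, name: str, compartment: str = "cytosol", tags: tuple[str, ...] = ()):
        if name not in self.species:
            amount = INITIAL_AMOUNTS.get(name, 0.0)
            self.species[name] = Species(name, compartment, amount, frozenset(tags))

    def _param(self, name: str) -> Param:
        return Param(name, self.params[name])

    def rxn(self, rid, reactants, products, *, kf, kr=None, tags=(), source="core"):
        for s in (*reactants, *products):
            self.sp(s)
        consts = {"kf": self._param(kf)}
        law = Law.MASS_ACTION_IRREVERSIBLE
        if kr is not None:
            consts["kr"] = self._param(kr)
            law = Law.MASS_ACTION_REVERSIBLE
        self.reactions.append(
            Reaction(rid, tuple(reactants), tuple(products), law, consts,
                     frozenset(tags), source))

    def catalysis(self, rid, enzyme, substrate, products, kon, koff, kcat,
                  tags=(), source="core"):
        """Explicit two-step enzymatic conversion: bind, then catalyse."""
        inter = complex_name(enzyme, substrate)
        self.rxn(f"{rid}.bind", (enzyme, substrate), (inter,), kf=kon, kr=koff,
                 tags=tags, source=source)
        self.rxn(f"{rid}.cat", (inter,), (enzyme, *products), kf=kcat,
                 tags=tags, source=source)


def build_egfr_network(params: dict[str, float] | None = None,
                       pad_to_cardinalities: bool = True) -> Model:
    """Build the EGFR-associated network model.

    Parameters
    ----------
    params
        Overrides for entries of :data:`DEFAULT_PARAMS`.
    pad_to_cardinalities
        Pad the table with inert reserve entries so that the structural
        counts are exactly 160 species / 243 reactions / 145 parameters /
        28 nonzero initial amounts.  Disable to obtain the bare mechanistic
        core (identical dynamics).
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ModelError(f"unknown parameter(s): {sorted(unknown)}")
        p.update(params)
    b = _Assembler(p)

    # --- receptor layer ---------------------------------------------------
    le = complex_name("EGF", "EGFR")                     # ligand-bound monomer
    dim = complex_name("EGF", "EGF", "EGFR", "EGFR")     # unphosphorylated dimer
    rp = _rp()                                           # active receptor
    b.species["EGF"] = Species("EGF", "membrane", INITIAL_AMOUNTS["EGF"],
                               frozenset({"stimulus:EGF"}))
    b.sp("EGFR", "membrane")
    b.rxn("r_egf_bind", ("EGF", "EGFR"), (le,), kf="k_egf_on", kr="k_egf_off",
          tags=("egf_binding",))
    b.rxn("r_dimerize", (le, le), (dim,), kf="k_dim_on", kr="k_dim_off",
          tags=("dimerization",))
    b.rxn("r_transphos", (dim,), (rp,), kf="k_rtk", tags=("transphosphorylation",))
    b.rxn("r_rp_dephos", (rp,), (dim,), kf="k_rtk_off")
    b.rxn("r_int_rp", (rp,), ("EGFRi", "EGFRi"), kf="k_int_rp", tags=("internalization",))
    b.rxn("r_int_le", (le,), ("EGFRi",), kf="k_int_le", tags=("internalization",))
    b.rxn("r_int_dim", (dim,), ("EGFRi", "EGFRi"), kf="k_int_d", tags=("internalization",))
    # Ligand-activated receptor internalizes together with its docked cargo
    # (the cargo is degraded with the receptor, as in classic receptor-level
    # models); these reactions are added after the docking sections below.

    # --- Shc/Grb2/SOS docking (ERK arm) ------------------------------------
    rsgs = _rp("p-Shc", "Grb2", "SOS")
    b.rxn("r_shc_bind", (rp, "Shc"), (_rp("Shc"),), kf="k_shc_on", kr="k_shc_off",
          tags=("shc_grb2_sos",))
    b.rxn("r_shc_phos", (_rp("Shc"),), (_rp("p-Shc"),), kf="k_shc_phos",
          tags=("shc_grb2_sos",))
    b.rxn("r_grb2_sos", ("Grb2", "SOS"), (complex_name("Grb2", "SOS"),),
          kf="k_gs_on", kr="k_gs_off", tags=("shc_grb2_sos",))
    b.rxn("r_rsgs_bind", (_rp("p-Shc"), complex_name("Grb2", "SOS")), (rsgs,),
          kf="k_rsgs_on", kr="k_rsgs_off", tags=("shc_grb2_sos",))
    b.rxn("r_pshc_rel", (_rp("p-Shc"),), (rp, "p-Shc"), kf="k_shc_rel")
    b.rxn("r_pshc_dp", ("p-Shc",), ("Shc",), kf="k_shc_dp", tags=("phosphatase",))

    # ERK -> SOS negative feedback: active ERK phosphorylates receptor-bound
    # SOS, which dissolves the Grb2-SOS module from the receptor.
    rsgs_p = _rp("p-Shc", "Grb2", "p-SOS")
    b.rxn("r_fb_bind", ("p-ERK", rsgs), (complex_name("p-ERK", rsgs),),
          kf="k_fb_on", kr="k_fb_off", tags=("feedback:ERK-SOS",))
    b.rxn("r_fb_cat", (complex_name("p-ERK", rsgs),), ("p-ERK", rsgs_p),
          kf="k_fb_cat", tags=("feedback:ERK-SOS",))
    b.rxn("r_fb_rel", (rsgs_p,), (_rp("p-Shc"), complex_name("Grb2", "p-SOS")),
          kf="k_fb_rel", tags=("feedback:ERK-SOS",))
    b.rxn("r_gps_rel", (complex_name("Grb2", "p-SOS"),), ("Grb2", "p-SOS"),
          kf="k_gps_rel", tags=("feedback:ERK-SOS",))
    b.rxn("r_sos_dp", ("p-SOS",), ("SOS",), kf="k_sos_dp", tags=("phosphatase",))

    # --- Ras cycle ----------------------------------------------------------
    b.catalysis("r_sos_ras", rsgs, "RasGDP", ("RasGTP",),
                "k_sosras_on", "k_sosras_off", "k_sosras_cat", tags=("ras_exchange",))
    b.catalysis("r_gap", "RasGAP", "RasGTP", ("RasGDP",),
                "k_gap_on", "k_gap_off", "k_gap_cat", tags=("ras_exchange",))
    b.rxn("r_ras_gtpase", ("RasGTP",), ("RasGDP",), kf="k_ras_gtpase",
          tags=("ras_exchange",))
    # GTP hydrolysis proceeds in the Ras-GTP:Raf encounter complex as well,
    # so Raf binding does not shelter Ras-GTP from inactivation
    b.rxn("r_ras_gtpase_c", (complex_name("RasGTP", "Raf"),), ("RasGDP", "Raf"),
          kf="k_ras_gtpase_c", tags=("ras_exchange",))
    b.rxn("r_ras_leak", ("RasGDP",), ("RasGTP",), kf="k_ras_leak",
          tags=("basal_leak",))

    # --- Raf/MEK/ERK cascade ------------------------------------------------
    b.catalysis("r_raf_act", "RasGTP", "Raf", ("p-Raf",),
                "k_raf_on", "k_raf_off", "k_raf_cat",
                tags=("raf_activation", "cascade:raf-mek-erk"))
    b.rxn("r_raf_dp", ("p-Raf",), ("Raf",), kf="k_raf_dp", tags=("phosphatase",))
    b.catalysis("r_rafpase", "RafPase", "p-Raf", ("Raf",),
                "k_mpase_on", "k_mpase_off", "k_mpase_cat", tags=("phosphatase",))
    b.rxn("r_raf_leak", ("Raf",), ("p-Raf",), kf="k_raf_leak", tags=("basal_leak",))

    b.catalysis("r_mek_act", "p-Raf", "MEK", ("p-MEK",),
                "k_mek_on", "k_mek_off", "k_mek_cat", tags=("cascade:raf-mek-erk",))
    b.rxn("r_mek_dp", ("p-MEK",), ("MEK",), kf="k_mek_dp", tags=("phosphatase",))
    b.catalysis("r_mekpase", "MEKPase", "p-MEK", ("MEK",),
                "k_mpase_on", "k_mpase_off", "k_mpase_cat", tags=("phosphatase",))

    b.catalysis("r_erk_act", "p-MEK", "ERK", ("p-ERK",),
                "k_erk_on", "k_erk_off", "k_erk_cat", tags=("cascade:raf-mek-erk",))
    b.rxn("r_erk_dp", ("p-ERK",), ("ERK",), kf="k_erk_dp", tags=("phosphatase",))
    b.catalysis("r_erkpase", "ERKPase", "p-ERK", ("ERK",),
                "k_mpase_on", "k_mpase_off", "k_mpase_cat", tags=("phosphatase",))

    # --- Grb2/Gab1/PI3K recruitment (AKT arm) -------------------------------
    rg = _rp("Grb2")
    rgg = _rp("Grb2", "Gab1")
    rgpg = _rp("Grb2", "p-Gab1")
    rgp = _rp("Grb2", "p-Gab1", "PI3K")                  # active PI3K module
    b.rxn("r_grb2_bind", (rp, "Grb2"), (rg,), kf="k_g_on", kr="k_g_off",
          tags=("gab1_pi3k",))
    b.rxn("r_gab1_bind", (rg, "Gab1"), (rgg,), kf="k_gab_on", kr="k_gab_off",
          tags=("gab1_pi3k",))
    b.rxn("r_gab1_phos", (rgg,), (rgpg,), kf="k_gab_phos", tags=("gab1_pi3k",))
    b.rxn("r_pi3k_bind", (rgpg, "PI3K"), (rgp,), kf="k_pi3k_on", kr="k_pi3k_off",
          tags=("gab1_pi3k",))
    b.rxn("r_pgab1_rel", (rgpg,), (rg, "p-Gab1"), kf="k_gab_rel")
    b.rxn("r_pgab1_dp", ("p-Gab1",), ("Gab1",), kf="k_gab_dp", tags=("phosphatase",))

    # --- PIP3 and AKT activation --------------------------------------------
    b.catalysis("r_pi3k", rgp, "PIP2", ("PIP3",),
                "k_pip_on", "k_pip_off", "k_pip_cat", tags=("pip3_akt",))
    b.catalysis("r_pten", "PTEN", "PIP3", ("PIP2",),
                "k_pten_on", "k_pten_off", "k_pten_cat", tags=("phosphatase",))
    akt_m = complex_name("AKT", "PIP3")
    akt_mp = complex_name("AKT", "PIP3", "PDK1")
    pakt_m = complex_name("p-AKT", "PIP3")
    b.rxn("r_akt_recruit", ("AKT", "PIP3"), (akt_m,), kf="k_aktp_on", kr="k_aktp_off",
          tags=("pip3_akt",))
    b.rxn("r_pdk1_bind", (akt_m, "PDK1"), (akt_mp,), kf="k_pdk_on", kr="k_pdk_off",
          tags=("pip3_akt",))
    b.rxn("r_pdk1_cat", (akt_mp,), ("PDK1", pakt_m), kf="k_pdk_cat",
          tags=("pip3_akt",))
    b.rxn("r_pakt_rel", (pakt_m,), ("p-AKT", "PIP3"), kf="k_pakt_rel",
          tags=("pip3_akt",))
    b.rxn("r_akt_dp", ("p-AKT",), ("AKT",), kf="k_akt_dp", tags=("phosphatase",))
    b.catalysis("r_pp2a", "PP2A", "p-AKT", ("AKT",),
                "k_pp2a_on", "k_pp2a_off", "k_pp2a_cat", tags=("phosphatase",))
    b.rxn("r_akt_leak", ("AKT",), ("p-AKT",), kf="k_akt_leak", tags=("basal_leak",))

    # --- Rac cycling and ROS generation -------------------------------------
    b.catalysis("r_rac_act", rgp, "RacGDP", ("RacGTP",),
                "k_rac_on", "k_rac_off", "k_rac_cat", tags=("ros_generation",))
    b.rxn("r_rac_off", ("RacGTP",), ("RacGDP",), kf="k_rac_gdp")
    b.rxn("r_ros_gen", ("RacGTP",), ("RacGTP", "ROS"), kf="k_ros_gen",
          tags=("ros_generation",))
    b.catalysis("r_scav", "ROSscav", "ROS", (),
                "k_scav_on", "k_scav_off", "k_scav_cat", tags=("ros_clearance",))
    b.rxn("r_ros_decay", ("ROS",), (), kf="k_ros_decay", tags=("ros_clearance",))

    # --- ROS -> ASK1 -> MKK -> p38 cascade ----------------------------------
    b.catalysis("r_ask1_act", "ROS", "ASK1", ("p-ASK1",),
                "k_ask1_on", "k_ask1_off", "k_ask1_cat",
                tags=("ros_ask1", "cascade:ask1-mkk-p38"))
    b.rxn("r_ask1_dp", ("p-ASK1",), ("ASK1",), kf="k_ask1_dp", tags=("phosphatase",))
    b.catalysis("r_ask1pase", "ASK1Pase", "p-ASK1", ("ASK1",),
                "k_spase_on", "k_spase_off", "k_spase_cat", tags=("phosphatase",))
    b.rxn("r_ask1_leak", ("ASK1",), ("p-ASK1",), kf="k_ask1_leak", tags=("basal_leak",))

    b.catalysis("r_mkk_act", "p-ASK1", "MKK", ("p-MKK",),
                "k_mkk_on", "k_mkk_off", "k_mkk_cat", tags=("cascade:ask1-mkk-p38",))
    b.rxn("r_mkk_dp", ("p-MKK",), ("MKK",), kf="k_mkk_dp", tags=("phosphatase",))
    b.catalysis("r_mkkpase", "MKKPase", "p-MKK", ("MKK",),
                "k_spase_on", "k_spase_off", "k_spase_cat", tags=("phosphatase",))

    b.catalysis("r_p38_act", "p-MKK", "p38", ("p-p38",),
                "k_p38_on", "k_p38_off", "k_p38_cat", tags=("cascade:ask1-mkk-p38",))
    b.rxn("r_p38_dp", ("p-p38",), ("p38",), kf="k_p38_dp", tags=("phosphatase",))
    b.catalysis("r_p38pase", "p38Pase", "p-p38", ("p38",),
                "k_spase_on", "k_spase_off", "k_spase_cat", tags=("phosphatase",))

    # --- AKT -> ASK1 inhibitory crosstalk ------------------------------------
    # Active AKT phosphorylates ASK1 on its inhibitory site (ASK1i), acting on
    # both the inactive and the activated kinase; ASK1i slowly recovers.
    b.catalysis("r_x_ask1", "p-AKT", "ASK1", ("ASK1i",),
                "k_x_on", "k_x_off", "k_x_cat", tags=("crosstalk:AKT-ASK1",))
    b.catalysis("r_x_pask1", "p-AKT", "p-ASK1", ("ASK1i",),
                "k_x_on", "k_x_off", "k_x_cat", tags=("crosstalk:AKT-ASK1",))
    b.rxn("r_ask1_recover", ("ASK1i",), ("ASK1",), kf="k_ask1_rec",
          tags=("crosstalk:AKT-ASK1",))

    # --- internalization of docked receptor complexes ------------------------
    # Every receptor-scaffold complex is cleared at the active-receptor
    # internalization rate; the scaffolded adaptors are degraded with it.
    docked = [_rp("Shc"), _rp("p-Shc"), rsgs, rg, rgg, rgpg, rgp]
    for i, name in enumerate(docked, start=1):
        b.rxn(f"r_int_cplx{i}", (name,), ("EGFRi", "EGFRi"), kf="k_int_rp",
              tags=("internalization",))

    model = Model(list(b.species.values()), list(b.reactions),
                  metadata={"name": "egfr_network", "core_species": len(b.species),
                            "core_reactions": len(b.reactions)})
    if pad_to_cardinalities:
        model = _pad(model, b)
    report = validate_model(model)
    if report:  # pragma: no cover - construction bug guard
        raise ModelError("fixture failed validation: " + "; ".join(report[:5]))
    return model


def _pad(model: Model, b: _Assembler) -> Model:
    """Pad with inert reserve entries to the printed cardinalities.

    Reserve species start at zero and only ever appear as reactants of other
    reserve reactions, so they carry no flux; they stand in for the complex
    intermediates of the published table that the main text does not name.
    """
    n_sp = len(model.species)
    n_rx = len(model.reactions)
    n_par = model.n_parameters
    s_pad = N_SPECIES - n_sp
    r_pad = N_REACTIONS - n_rx
    p_pad = N_PARAMETERS - n_par
    if s_pad < 2 or r_pad < s_pad - 1 or p_pad < 1:
        raise ModelError(
            f"core too large to pad: species {n_sp}, reactions {n_rx}, "
            f"parameters {n_par}")

    pad_species = [Species(f"Rsv{i:03d}") for i in range(1, s_pad + 1)]
    pad_params = [Param(f"k_rsv{i:02d}", 0.01 + 0.001 * i) for i in range(1, p_pad + 1)]
    reactions = []
    names = [s.name for s in pad_species]
    for j in range(r_pad):
        a = names[j % s_pad]
        c = names[(j + 1) % s_pad]
        par = pad_params[j % p_pad]
        reactions.append(Reaction(
            f"r_rsv{j + 1:03d}", (a,), (c,), Law.MASS_ACTION_IRREVERSIBLE,
            {"kf": par}, frozenset({"reconstructed"}), "reconstructed"))

    out = Model(model.species + pad_species, model.reactions + reactions,
                dict(model.metadata))
    assert len(out.species) == N_SPECIES
    assert len(out.reactions) == N_REACTIONS
    assert out.n_parameters == N_PARAMETERS
    assert len(out.nonzero_initial_species()) == N_NONZERO_INITIALS
    return out


# ---------------------------------------------------------------------------
# structural variants
# ---------------------------------------------------------------------------

_VARIANT_KINDS = {
    "remove_internalization",
    "clamp_EGF",
    "remove_crosstalk_AKT_ASK1",
    "remove_ROS",
    "inhibit_EGFR_at_time",
}


@dataclass(frozen=True)
class VariantSpec:
    """A structural intervention on the network.

    kinds
    -----
    ``remove_internalization``
        Delete all reactions tagged ``internalization`` (sustained-activation
        setting).
    ``clamp_EGF``
        Hold EGF constant; optional ``level`` (nM) overrides the initial dose.
    ``remove_crosstalk_AKT_ASK1``
        Delete the AKT->ASK1 inhibitory link.
    ``remove_ROS``
        Delete the ROS species and every reaction touching it.
    ``inhibit_EGFR_at_time``
        Timed event: at ``time`` (min) active receptor species are reset to
        their basal values and receptor trans-phosphorylation falls to a
        basal leak (``leak_factor``, default 1e-4 of the active rate).
    """

    kind: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _VARIANT_KINDS:
            raise ModelError(f"unknown variant kind {self.kind!r}")
        if self.kind == "inhibit_EGFR_at_time" and "time" not in self.parameters:
            raise ModelError("inhibit_EGFR_at_time requires a 'time' parameter")


def _drop_orphans(model: Model) -> Model:
    referenced: set[str] = set()
    for rxn in model.reactions:
        referenced.update(rxn.reactants)
        referenced.update(rxn.products)
    return Model([s for s in model.species if s.name in referenced],
                 list(model.reactions), dict(model.metadata))


def _remove_tagged(model: Model, tag: str) -> Model:
    keep = [r for r in model.reactions if tag not in r.tags]
    if len(keep) == len(model.reactions):
        raise ModelError(f"no reaction carries tag {tag!r}")
    return _drop_orphans(Model(list(model.species), keep, dict(model.metadata)))


def apply_variant(model: Model, variant: VariantSpec) -> Model:
    """Return a new model with the variant applied; the input is unchanged."""
    if variant.kind == "remove_internalization":
        return _remove_tagged(model, "internalization")
    if variant.kind == "remove_crosstalk_AKT_ASK1":
        return _remove_tagged(model, "crosstalk:AKT-ASK1")
    if variant.kind == "remove_ROS":
        if "ROS" not in model.species_names:
            raise ModelError("model has no ROS species")
        keep = [r for r in model.reactions
                if "ROS" not in r.reactants and "ROS" not in r.products]
        out = Model([s for s in model.species if s.name != "ROS"], keep,
                    dict(model.metadata))
        return _drop_orphans(out)
    if variant.kind == "clamp_EGF":
        level = variant.parameters.get("level")
        species = []
        found = False
        for s in model.species:
            if "stimulus:EGF" in s.role_tags or s.name == "EGF":
                found = True
                s = replace(s, role_tags=s.role_tags | {"clamped"},
                            initial_amount=float(level) if level is not None
                            else s.initial_amount)
            species.append(s)
        if not found:
            raise ModelError("model has no EGF stimulus species")
        return Model(species, list(model.reactions), dict(model.metadata))
    if variant.kind == "inhibit_EGFR_at_time":
        meta = dict(model.metadata)
        events = list(meta.get("events", []))
        events.append((float(variant.parameters["time"]), variant))
        meta["events"] = events
        return Model(list(model.species), list(model.reactions), meta)
    raise ModelError(f"unknown variant kind {variant.kind!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# structural queries used by tests and reports
# ---------------------------------------------------------------------------

def reaction_graph(model: Model) -> "nx.DiGraph":
    """Directed species graph: an edge reactant -> product per reaction."""
    g = nx.DiGraph()
    g.add_nodes_from(model.species_names)
    for rxn in model.reactions:
        for a in rxn.reactants:
            for c in rxn.products:
                g.add_edge(a, c)
    return g


def is_reachable(model: Model, source: str, target: str) -> bool:
    g = reaction_graph(model)
    return nx.has_path(g, source, target)


def receptor_active_species(model: Model) -> list[str]:
    """Species reset by the EGFR-inhibition event: phosphorylated or
    dimerized receptor forms."""
    out = []
    for s in model.species:
        toks = species_tokens(s.name)
        if "p-EGFR" in toks or moiety_count(s.name, "EGFR") >= 2:
            out.append(s.name)
    return out
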