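"""Synthetic study generator with known ground truth.

Emulates a two-season colony study of a socially monogamous passerine
with high extra-pair paternity: ~24 breeding sites, ~108 mothers and ~95
fathers producing ~500 offspring, ~41% of them sired by extra-pair males
with nest-level clustering such that about two thirds of nests contain at
least one extra-pair young. Four correlated color traits (theta, phi,
r_A, brightness) are generated under the additive model

    y = mu + fixed effects + a + c_nest + m_mother + e,

with breeding values ``a`` dropped down the pedigree (founders
MVN(0, G); offspring = midparent + Mendelian deviate MVN(0, G/2), no
inbreeding), nest effects c ~ MVN(0, C), maternal effects m ~ MVN(0, M),
and residuals e ~ MVN(0, R). Adult-stage phenotypes reuse the same
breeding value and maternal effect but draw a fresh residual and carry
no nest effect: adult feathers are regrown far from the natal nest, so
nestling -> adult persistence is governed by the (V_A + V_ME) share.

Genotypes are produced by Mendelian gene dropping at 7 unlinked
microsatellite loci (default 8 equifrequent alleles each), and
spectrometer-style triplicate reflectance spectra come from a
two-parameter melanin family (pigment concentration scales reflectance
down; eumelanin:pheomelanin balance tilts the long-vs-short-wavelength
slope).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .pedigree import topological_order

__all__ = [
    "SimulationParams",
    "SyntheticStudy",
    "simulate_population",
    "simulate_matings",
    "simulate_genotypes",
    "simulate_phenotypes",
    "melanin_spectrum",
    "simulate_spectra",
    "simulate_study",
]

TRAITS = ("theta", "phi", "r_A", "brightness")

# Generating (co)variance diagonals on the standardized trait scale,
# patterned on the all-families variance-component modes (see docs/methods.md).
_G_DIAG = (0.34, 0.297, 0.332, 0.297)
_C_DIAG = (0.303, 0.304, 0.177, 0.293)
_R_DIAG = (0.393, 0.459, 0.512, 0.489)
# Multibrood preset adds a maternal component.
_G_DIAG_MB = (0.256, 0.28, 0.266, 0.186)
_C_DIAG_MB = (0.361, 0.274, 0.268, 0.217)
_M_DIAG_MB = (0.135, 0.14, 0.141, 0.145)
_R_DIAG_MB = (0.452, 0.493, 0.453, 0.523)


def _default_fixed_effects() -> dict[str, tuple[float, ...]]:
    # Year, date-within-year, and mass effects are small (only year was
    # influential in the reference analysis); sex effects reproduce the
    # dimorphism pattern: nestlings dimorphic in saturation/brightness
    # only, adults in all four metrics.
    return {
        "year": (0.082, 0.082, 0.082, 0.082),
        "date_2008": (0.026, 0.026, 0.026, 0.026),
        "date_2009": (-0.020, -0.020, -0.020, -0.020),
        "mass": (0.013, 0.013, 0.013, 0.013),
        "sex_nestling": (0.0, 0.0, 0.209, -0.497),
        "sex_adult": (-1.251, 1.181, 0.464, -0.844),
    }


@dataclass
class SimulationParams:
    """Generating parameters for one synthetic study."""

    n_sites: int = 24
    n_mothers: int = 108
    n_fathers: int = 95
    broods_per_mother: dict[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.25, 3: 0.05}
    )
    brood_size: dict[int, float] = field(
        default_factory=lambda: {2: 0.15, 3: 0.30, 4: 0.35, 5: 0.15, 6: 0.05}
    )
    epp_rate: float = 0.41
    # Intraclass correlation of the nest-level Beta-Binomial; 0.37 puts
    # ~67% of nests at >= 1 extra-pair young given the brood-size mix.
    epp_overdispersion: float = 0.37
    n_loci: int = 7
    alleles_per_locus: tuple[int, ...] | None = None  # default: 8 each
    allele_freqs: list[np.ndarray] | None = None  # default: equifrequent
    G: np.ndarray = field(default_factory=lambda: np.diag(_G_DIAG))
    C: np.ndarray = field(default_factory=lambda: np.diag(_C_DIAG))
    M: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))
    R: np.ndarray = field(default_factory=lambda: np.diag(_R_DIAG))
    fixed_effects: dict[str, tuple[float, ...]] = field(
        default_factory=_default_fixed_effects
    )
    trait_means: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    years: tuple[int, ...] = (2008, 2009)
    seed: int = 0

    @classmethod
    def multibrood(cls, seed: int = 0) -> "SimulationParams":
        """Preset for the maternal-effects design: every mother has >= 2
        broods and a nonzero maternal (co)variance component."""
        return cls(
            n_mothers=32,
            n_fathers=45,
            n_sites=12,
            broods_per_mother={2: 0.7, 3: 0.3},
            G=np.diag(_G_DIAG_MB),
            C=np.diag(_C_DIAG_MB),
            M=np.diag(_M_DIAG_MB),
            R=np.diag(_R_DIAG_MB),
            seed=seed,
        )

    def resolved_allele_freqs(self) -> list[np.ndarray]:
        if self.allele_freqs is not None:
            return [np.asarray(f, dtype=float) for f in self.allele_freqs]
        counts = self.alleles_per_locus or (8,) * self.n_loci
        return [np.full(k, 1.0 / k) for k in counts]

    def validate(self) -> None:
        for name in ("n_sites", "n_mothers", "n_fathers", "n_loci"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("broods_per_mother", "brood_size"):
            dist = getattr(self, name)
            probs = np.array(list(dist.values()), dtype=float)
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a probability distribution")
            if any(k < 1 for k in dist):
                raise ValueError(f"{name} support must be positive integers")
        if not 0.0 <= self.epp_rate <= 1.0:
            raise ValueError("epp_rate must lie in [0, 1]")
        if not 0.0 <= self.epp_overdispersion < 1.0:
            raise ValueError("epp_overdispersion must lie in [0, 1)")
        for name in ("G", "C", "M", "R"):
            V = np.asarray(getattr(self, name), dtype=float)
            if V.shape != (4, 4) or not np.allclose(V, V.T, atol=1e-12):
                raise ValueError(f"{name} must be a symmetric 4x4 matrix")
            if np.linalg.eigvalsh(V).min() < -1e-10:
                raise ValueError(f"{name} must be positive semidefinite")
        for f in self.resolved_allele_freqs():
            if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-12:
                raise ValueError("allele frequencies must sum to 1")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for key in ("G", "C", "M", "R"):
            d[key] = np.asarray(d[key]).tolist()
        if d["allele_freqs"] is not None:
            d["allele_freqs"] = [np.asarray(f).tolist() for f in d["allele_freqs"]]
        d["broods_per_mother"] = {str(k): v for k, v in d["broods_per_mother"].items()}
        d["brood_size"] = {str(k): v for k, v in d["brood_size"].items()}
        return d


@dataclass
class SyntheticStudy:
    """One complete generated study plus its generating truth."""

    params: SimulationParams
    adults: pd.DataFrame          # id, role, site
    social: pd.DataFrame          # offspring records (nest, parents, covariates)
    pedigree_truth: pd.DataFrame  # individual, dam, sire, is_extra_pair
    genotypes: pd.DataFrame       # individual, locus, allele1, allele2
    phenotypes: pd.DataFrame      # individual, stage, sex + 4 traits
    spectra: pd.DataFrame         # wavelength_nm + "<id>|rep<k>" columns
    latent: dict                  # breeding values / nest / maternal draws


def _draw_categorical(rng: np.random.Generator, dist: Mapping[int, float], size: int) -> np.ndarray:
    keys = np.array(sorted(dist))
    probs = np.array([dist[int(k)] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), size=size, p=probs)]


def simulate_population(params: SimulationParams, rng: np.random.Generator | None = None):
    """Draw the study skeleton: sites, pairings, nests, offspring slots.

    Returns ``(adults, social)`` DataFrames. Deterministic given the seed.
    """
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    mothers = [f"dam{i:03d}" for i in range(params.n_mothers)]
    fathers = [f"sire{i:03d}" for i in range(params.n_fathers)]
    mother_site = rng.integers(params.n_sites, size=params.n_mothers)
    father_site = rng.integers(params.n_sites, size=params.n_fathers)
    site_fathers: dict[int, list[str]] = {}
    for f, s in zip(fathers, father_site):
        site_fathers.setdefault(int(s), []).append(f)

    adults = pd.DataFrame(
        {
            "id": mothers + fathers,
            "role": ["mother"] * params.n_mothers + ["father"] * params.n_fathers,
            "site": np.concatenate([mother_site, father_site]),
        }
    )

    n_broods = _draw_categorical(rng, params.broods_per_mother, params.n_mothers)
    rows = []
    nest_no = 0
    off_no = 0
    for mi, mom in enumerate(mothers):
        site = int(mother_site[mi])
        pool = site_fathers.get(site) or fathers
        for _ in range(int(n_broods[mi])):
            nest = f"nest{nest_no:04d}"
            nest_no += 1
            dad = pool[rng.integers(len(pool))]
            year = int(params.years[rng.integers(len(params.years))])
            date = float(rng.uniform(0.0, 60.0))
            size = int(_draw_categorical(rng, params.brood_size, 1)[0])
            for _ in range(size):
                rows.append(
                    {
                        "individual": f"off{off_no:04d}",
                        "nest": nest,
                        "site": site,
                        "social_mother": mom,
                        "social_father": dad,
                        "year": year,
                        "sex": "M" if rng.random() < 0.5 else "F",
                        "date": date,
                        "mass": float(rng.normal(0.0, 1.0)),
                    }
                )
                off_no += 1
    return adults, pd.DataFrame(rows)


def simulate_matings(
    adults: pd.DataFrame,
    social: pd.DataFrame,
    epp_rate: float,
    epp_overdispersion: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign genetic sires: per-nest extra-pair probability from a Beta
    distribution with mean ``epp_rate``, extra-pair sires drawn uniformly
    from other males at the same site."""
    if social.empty:
        raise ValueError("no offspring in skeleton")
    fathers = adults.loc[adults["role"] == "father"]
    if epp_rate > 0 and len(fathers) < 2:
        raise ValueError("epp_rate > 0 requires at least two candidate sires")
    site_fathers = {
        int(s): list(sub["id"]) for s, sub in fathers.groupby("site")
    }
    all_fathers = list(fathers["id"])
    rows = []
    for nest, sub in social.groupby("nest", sort=True):
        if epp_overdispersion == 0.0 or epp_rate in (0.0, 1.0):
            p = epp_rate
        else:
            phi = (1.0 - epp_overdispersion) / epp_overdispersion
            p = rng.beta(epp_rate * phi, (1.0 - epp_rate) * phi)
        for rec in sub.itertuples(index=False):
            is_ep = bool(rng.random() < p)
            if is_ep:
                pool = [
                    f for f in site_fathers.get(int(rec.site), [])
                    if f != rec.social_father
                ] or [f for f in all_fathers if f != rec.social_father]
                sire = pool[rng.integers(len(pool))]
            else:
                sire = rec.social_father
            rows.append(
                {
                    "individual": rec.individual,
                    "dam": rec.social_mother,
                    "sire": sire,
                    "is_extra_pair": is_ep,
                }
            )
    out = pd.DataFrame(rows)
    return out.set_index("individual").loc[social["individual"]].reset_index()


def simulate_genotypes(
    pedigree_truth: pd.DataFrame,
    allele_freqs: list[np.ndarray],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mendelian gene dropping: founders i.i.d. from allele frequencies,
    offspring receive one uniformly chosen allele from each genetic parent
    per locus. No genotyping error."""
    ped = topological_order(
        pedigree_truth.rename(columns={"individual": "id"})[["id", "dam", "sire"]]
        if "individual" in pedigree_truth.columns
        else pedigree_truth
    )
    # add referenced parents as founders
    known = set(ped["id"])
    founders = sorted(
        {p for p in pd.concat([ped["dam"], ped["sire"]]) if p and p not in known}
    )
    full = pd.concat(
        [pd.DataFrame({"id": founders, "dam": "", "sire": ""}), ped],
        ignore_index=True,
    )
    genos: dict[str, list[tuple[int, int]]] = {}
    rows = []
    for rec in full.itertuples(index=False):
        pair_list = []
        for li, freqs in enumerate(allele_freqs):
            alleles = []
            for parent in (rec.dam, rec.sire):
                if parent:
                    pg = genos[parent][li]
                    alleles.append(pg[rng.integers(2)])
                else:
                    alleles.append(int(rng.choice(len(freqs), p=freqs)) + 1)
            pair = (int(alleles[0]), int(alleles[1]))
            pair_list.append(pair)
            rows.append(
                {
                    "individual": rec.id,
                    "locus": f"loc{li + 1}",
                    "allele1": pair[0],
                    "allele2": pair[1],
                }
            )
        genos[rec.id] = pair_list
    return pd.DataFrame(rows)


def _sqrt_psd(V: np.ndarray) -> np.ndarray:
    w, Q = np.linalg.eigh(np.asarray(V, dtype=float))
    w = np.clip(w, 0.0, None)
    return Q * np.sqrt(w)


def simulate_phenotypes(
    pedigree_truth: pd.DataFrame,
    social: pd.DataFrame,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Generate nestling and adult 4-trait phenotypes for every offspring.

    Returns ``(phenotypes, latent)``; latent holds the breeding values and
    the nest / maternal draws for oracle checks.
    """
    params.validate()
    t = len(TRAITS)
    Bg = _sqrt_psd(params.G)
    Bg_half = _sqrt_psd(0.5 * np.asarray(params.G))
    Bc = _sqrt_psd(params.C)
    Bm = _sqrt_psd(params.M)
    Br = _sqrt_psd(params.R)

    ped = pedigree_truth.rename(columns={"individual": "id"})
    known = set(ped["id"])
    founders = sorted(
        {p for p in pd.concat([ped["dam"], ped["sire"]]) if p and p not in known}
    )
    a: dict[str, np.ndarray] = {}
    for f in founders:
        a[f] = Bg @ rng.standard_normal(t)
    for rec in topological_order(ped[["id", "dam", "sire"]]).itertuples(index=False):
        if rec.id in a:
            continue
        mid = np.zeros(t)
        n_par = 0
        for parent in (rec.dam, rec.sire):
            if parent:
                mid += a[parent]
                n_par += 1
        a[rec.id] = 0.5 * mid + Bg_half @ rng.standard_normal(t)

    nests = sorted(social["nest"].unique())
    c = {k: Bc @ rng.standard_normal(t) for k in nests}
    moms = sorted(social["social_mother"].unique())
    m = {k: Bm @ rng.standard_normal(t) for k in moms}

    fe = {k: np.asarray(v, dtype=float) for k, v in params.fixed_effects.items()}
    mu = np.asarray(params.trait_means, dtype=float)
    base_year = min(params.years)
    rows = []
    for rec in social.itertuples(index=False):
        sex_sign = 0.5 if rec.sex == "M" else -0.5
        date_c = (rec.date - 30.0) / 15.0
        fixed = (
            fe["year"] * (rec.year != base_year)
            + fe[f"date_{rec.year}" if f"date_{rec.year}" in fe else "date_2008"] * date_c
            + fe["mass"] * rec.mass
            + fe["sex_nestling"] * sex_sign
        )
        core = mu + a[rec.individual] + m[rec.social_mother]
        nestling = core + fixed + c[rec.nest] + Br @ rng.standard_normal(t)
        adult = core + fe["sex_adult"] * sex_sign + Br @ rng.standard_normal(t)
        for stage, vals in (("nestling", nestling), ("adult", adult)):
            row = {"individual": rec.individual, "stage": stage, "sex": rec.sex}
            row.update(dict(zip(TRAITS, vals)))
            rows.append(row)
    latent = {"a": a, "c": c, "m": m}
    return pd.DataFrame(rows), latent


# --- reflectance spectra -------------------------------------------------

MAX_REFLECTANCE = 70.0  # percent, the family's zero-pigment ceiling


def melanin_spectrum(
    wavelengths: np.ndarray,
    concentration: float,
    balance: float = 0.5,
) -> np.ndarray:
    """Melanin-like monotone reflectance curve.

    ``R(lambda) = R0 * exp(-concentration * (1 + balance * (1 - w)))`` with
    ``w`` the position in the 300-700 nm window. Zero concentration gives
    a flat spectrum at the family ceiling; higher concentration strictly
    lowers mean reflectance; ``balance`` (eumelanin:pheomelanin) tilts the
    long- vs short-wavelength slope.
    """
    if concentration < 0 or balance < 0:
        raise ValueError("concentration and balance must be nonnegative")
    wl = np.asarray(wavelengths, dtype=float)
    w = (wl - 300.0) / 400.0
    return MAX_REFLECTANCE * np.exp(-concentration * (1.0 + balance * (1.0 - w)))


def simulate_spectra(
    samples: pd.DataFrame,
    n_replicates: int = 3,
    noise_sd: float = 0.5,
    rng: np.random.Generator | None = None,
    wavelengths: np.ndarray | None = None,
) -> pd.DataFrame:
    """Triplicate spectrometer-style scans for each sample.

    ``samples`` has columns sample_id, concentration, balance. Gaussian
    replicate noise with SD ``noise_sd`` (percent reflectance) is added
    and clipped at zero. Returns the wide spectra table
    (wavelength_nm + one column per sample and replicate).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = rng or np.random.default_rng(0)
    wl = np.arange(300.0, 701.0, 2.0) if wavelengths is None else np.asarray(wavelengths, dtype=float)
    data = {"wavelength_nm": wl}
    for rec in samples.itertuples(index=False):
        mean = melanin_spectrum(wl, rec.concentration, rec.balance)
        for k in range(1, n_replicates + 1):
            noisy = mean + (rng.standard_normal(wl.size) * noise_sd if noise_sd > 0 else 0.0)
            data[f"{rec.sample_id}|rep{k}"] = np.clip(noisy, 0.0, None)
    return pd.DataFrame(data)


def simulate_study(params: SimulationParams | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study from one seed."""
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    adults, social = simulate_population(params, rng)
    pedigree_truth = simulate_matings(
        adults, social, params.epp_rate, params.epp_overdispersion, rng
    )
    # every adult must be genotyped (a fully cuckolded social father is
    # still typed in the field), so adults enter as explicit founders
    drop_ped = pd.concat(
        [
            pd.DataFrame({"id": adults["id"], "dam": "", "sire": ""}),
            pedigree_truth.rename(columns={"individual": "id"})[["id", "dam", "sire"]],
        ],
        ignore_index=True,
    )
    genotypes = simulate_genotypes(drop_ped, params.resolved_allele_freqs(), rng)
    phenotypes, latent = simulate_phenotypes(pedigree_truth, social, params, rng)
    # spectra for the nestling stage: pigment parameters derived from the
    # nestling brightness (concentration) and theta (balance) trait values
    nestl = phenotypes[phenotypes["stage"] == "nestling"].set_index("individual")
    samples = pd.DataFrame(
        {
            "sample_id": nestl.index,
            "concentration": np.exp(-0.35 * nestl["brightness"].to_numpy()) * 0.8,
            "balance": np.exp(0.30 * nestl["theta"].to_numpy()) * 0.5,
        }
    )
    spectra = simulate_spectra(samples, rng=rng)
    return SyntheticStudy(
        params=params,
        adults=adults,
        social=social,
        pedigree_truth=pedigree_truth,
        genotypes=genotypes,
        phenotypes=phenotypes,
        spectra=spectra,
        latent=latent,
    )
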