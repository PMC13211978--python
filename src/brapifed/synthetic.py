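"""Self-contained synthetic federation data with a planted marker-trait effect.

The generator emulates the data landscape the proxy is built for: a
passport/phenotype database holding germplasm, studies and trait
observations for several crops, plus one variant-browser backend per crop
holding samples, variants, callsets and a genotype matrix derived from VCF
(unphased genotype strings "0/0", "0/1", "1/1", missing ".").

Population model
----------------
Per variant an alternate-allele frequency is drawn from Uniform(0.1, 0.9)
and genotypes follow Hardy-Weinberg proportions at that frequency,
independently across germplasm (no linkage disequilibrium).  One designated
variant of the first crop carries a trait effect: each observation of the
quantitative trait is drawn as

    value = mu + beta * dosage + Normal(0, sigma)

where dosage is the germplasm's count of alternate alleles at the planted
variant (0 for all germplasm of other crops).  Genotypes are drawn once per
germplasm, so all callsets of a germplasm agree; missingness is applied to
reported matrix cells only, never to the latent dosage driving the trait.

Defaults model a small genebank panel: 60 germplasm per crop across two
crops (120 callsets), plant height around 100 cm with sigma = 5 cm, and a
planted effect of beta = 15 cm per alternate allele (three noise SDs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

GENOTYPES = ("0/0", "0/1", "1/1")


@dataclass(frozen=True)
class WorldSpec:
    """Counts and effect parameters of a synthetic federation."""

    crops: tuple[str, ...] = ("barley", "wheat")
    germplasm_per_crop: int = 60
    samples_per_germplasm: int = 1
    studies_per_crop: int = 3
    observations_per_germplasm: int = 2
    variants_per_crop: int = 12
    #: chromosome label per crop (crop i defaults to f"{6+i}H")
    chromosomes: tuple[str, ...] | None = None
    #: base position of the variant cluster (bp, 1-based)
    position_base: int = 17_000_000
    #: spacing between consecutive variants (bp)
    position_step: int = 1_000
    #: index (within the first crop's variants) of the effect variant
    planted_variant_index: int = 5
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.05
    trait_name: str = "Plant_height"
    trait_unit: str = "cm"
    mu: float = 100.0
    sigma: float = 5.0
    beta: float = 15.0  # trait units per alternate allele; 3 * sigma
    study_years: tuple[int, ...] = (2019, 2020, 2021)
    institutes: tuple[str, ...] = ("IPK", "WUR", "INRAE", "Kew")
    countries: tuple[str, ...] = ("DEU", "NLD", "FRA", "GBR", "ESP")

    def validate(self) -> None:
        if min(self.germplasm_per_crop, self.samples_per_germplasm,
               self.studies_per_crop, self.observations_per_germplasm,
               self.variants_per_crop) < 1:
            raise ValueError("all entity counts must be positive")
        if not self.crops:
            raise ValueError("at least one crop required")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing-genotype rate must be in [0, 1)")
        if not 0 <= self.planted_variant_index < self.variants_per_crop:
            raise ValueError("planted variant index out of range")
        lo, hi = self.allele_freq_range
        if not 0 < lo <= hi < 1:
            raise ValueError("allele frequency range must lie inside (0, 1)")


@dataclass
class CropData:
    """Genotype-backend content for one crop."""

    crop: str
    samples: list[dict]
    variants: list[dict]
    callsets: list[dict]
    #: genotype grid, rows by variants x columns by callsets
    matrix: list[list[str]]
    allele_freqs: list[float]


@dataclass
class SyntheticWorld:
    """A generated federation fixture with closed linkage."""

    spec: WorldSpec
    seed: int
    germplasm: list[dict]
    studies: list[dict]
    observation_variables: list[dict]
    observations: list[dict]
    crops: dict[str, CropData]
    #: germplasmDbId -> latent alternate-allele dosage at the planted variant
    dosages: dict[str, int]

    @property
    def planted_variant_id(self) -> str:
        crop = self.spec.crops[0]
        return self.crops[crop].variants[self.spec.planted_variant_index]["variantDbId"]

    @property
    def planted_chromosome(self) -> str:
        crop = self.spec.crops[0]
        return self.crops[crop].variants[self.spec.planted_variant_index]["referenceName"]

    @property
    def planted_position(self) -> int:
        crop = self.spec.crops[0]
        return self.crops[crop].variants[self.spec.planted_variant_index]["start"]

    def to_dict(self) -> dict[str, Any]:
        return {
            "spec": asdict(self.spec),
            "seed": self.seed,
            "germplasm": self.germplasm,
            "studies": self.studies,
            "observation_variables": self.observation_variables,
            "observations": self.observations,
            "crops": {name: asdict(c) for name, c in self.crops.items()},
            "dosages": self.dosages,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")


def _chromosome_for(spec: WorldSpec, crop_index: int) -> str:
    if spec.chromosomes is not None:
        return spec.chromosomes[crop_index % len(spec.chromosomes)]
    return f"{6 + crop_index}H"


def generate_world(spec: WorldSpec | None = None, seed: int = 0) -> SyntheticWorld:
    """Deterministically generate a synthetic federation for ``seed``."""
    spec = spec or WorldSpec()
    spec.validate()
    rng = np.random.default_rng(seed)

    germplasm: list[dict] = []
    studies: list[dict] = []
    observations: list[dict] = []
    crops: dict[str, CropData] = {}
    dosages: dict[str, int] = {}

    observation_variables = [
        {
            "observationVariableDbId": "OV1",
            "observationVariableName": spec.trait_name,
            "commonCropName": spec.crops[0],
            "scale": {"units": spec.trait_unit},
        }
    ]

    obs_counter = 0
    for ci, crop in enumerate(spec.crops):
        chrom = _chromosome_for(spec, ci)
        tag = crop[:3].upper()

        crop_studies = []
        for k in range(spec.studies_per_crop):
            year = spec.study_years[k % len(spec.study_years)]
            crop_studies.append(
                {
                    "studyDbId": f"ST-{tag}-{k + 1}",
                    "studyName": f"{crop} field trial {year}",
                    "studyType": "phenotyping",
                    "commonCropName": crop,
                    "year": year,
                }
            )
        studies.extend(crop_studies)

        crop_germplasm = []
        for g in range(spec.germplasm_per_crop):
            gid = f"{tag}{g + 1:04d}"
            crop_germplasm.append(
                {
                    "germplasmDbId": gid,
                    "germplasmName": f"{crop}-line-{g + 1}",
                    "commonCropName": crop,
                    "instituteName": str(rng.choice(spec.institutes)),
                    "countryOfOriginCode": str(rng.choice(spec.countries)),
                }
            )
        germplasm.extend(crop_germplasm)

        # variants along one chromosome, position-sorted at the source
        variants = [
            {
                "variantDbId": f"V{v + 1:04d}",
                "variantNames": [f"{crop}_snp_{v + 1}"],
                "referenceName": chrom,
                "start": spec.position_base + v * spec.position_step,
                "end": spec.position_base + v * spec.position_step,
                "variantType": "SNV",
            }
            for v in range(spec.variants_per_crop)
        ]

        samples = []
        callsets = []
        for g, grec in enumerate(crop_germplasm):
            for s in range(spec.samples_per_germplasm):
                idx = g * spec.samples_per_germplasm + s
                sid = f"S{idx + 1:04d}"
                samples.append(
                    {
                        "sampleDbId": sid,
                        "sampleName": f"{crop}-sample-{idx + 1}",
                        # external reference into the passport database
                        "germplasmDbId": grec["germplasmDbId"],
                    }
                )
                callsets.append(
                    {
                        "callSetDbId": f"C{idx + 1:04d}",
                        "callSetName": f"{crop}-callset-{idx + 1}",
                        "sampleDbId": sid,
                    }
                )

        lo, hi = spec.allele_freq_range
        freqs = rng.uniform(lo, hi, size=spec.variants_per_crop)
        n_g = spec.germplasm_per_crop
        # genotype index per (variant, germplasm): 0, 1 or 2 alt alleles
        geno_idx = np.empty((spec.variants_per_crop, n_g), dtype=np.int64)
        for v, p in enumerate(freqs):
            probs = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]
            geno_idx[v] = rng.choice(3, size=n_g, p=probs)

        planted_local = spec.planted_variant_index if ci == 0 else None
        for g, grec in enumerate(crop_germplasm):
            dosages[grec["germplasmDbId"]] = (
                int(geno_idx[planted_local, g]) if planted_local is not None else 0
            )

        # expand to callsets (all callsets of a germplasm share its genotype),
        # then mask reported cells with the missing rate
        n_cs = len(callsets)
        matrix: list[list[str]] = []
        mask = rng.random((spec.variants_per_crop, n_cs)) < spec.missing_rate
        for v in range(spec.variants_per_crop):
            row = []
            for c in range(n_cs):
                g = c // spec.samples_per_germplasm
                row.append("." if mask[v, c] else GENOTYPES[geno_idx[v, g]])
            matrix.append(row)

        crops[crop] = CropData(
            crop=crop,
            samples=samples,
            variants=variants,
            callsets=callsets,
            matrix=matrix,
            allele_freqs=[float(f) for f in freqs],
        )

        for grec in crop_germplasm:
            dose = dosages[grec["germplasmDbId"]]
            for _ in range(spec.observations_per_germplasm):
                obs_counter += 1
                study = crop_studies[int(rng.integers(len(crop_studies)))]
                value = spec.mu + spec.beta * dose + rng.normal(0.0, spec.sigma)
                observations.append(
                    {
                        "observationDbId": f"OBS{obs_counter:06d}",
                        "germplasmDbId": grec["germplasmDbId"],
                        "studyDbId": study["studyDbId"],
                        "observationVariableDbId": "OV1",
                        "observationVariableName": spec.trait_name,
                        "value": f"{value:.2f}",
                    }
                )

    return SyntheticWorld(
        spec=spec,
        seed=seed,
        germplasm=germplasm,
        studies=studies,
        observation_variables=observation_variables,
        observations=observations,
        crops=crops,
        dosages=dosages,
    )
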