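# gelquant

Quantitative analysis of 3D-bioprinted tumor-cell hydrogels: histomorphometry
of stained paraffin sections, immunohistochemistry (IHC) scoring, pore-size
distribution statistics and Young's-modulus extraction from uniaxial
compression curves — with a seeded synthetic-data generator that provides
exact ground truth for every measurement.

## The problem

Soft composite hydrogels (e.g. methacrylated gelatin with increasing
methacrylated alginate, GelMA/AlgMA) are bioprinted with tumor cells such as
neuroblastoma lines and cultured for weeks. Characterising how scaffold
stiffness shapes cell behaviour requires the same few quantities over and
over, measured reproducibly across conditions:

* **Mechanics** — the Young's modulus *E* (kPa), the slope of the engineering
  stress–strain curve σ(ε) over the linear elastic region of a compression
  test (σ = F/A₀, ε = Δh/h₀, with 1 mN/mm² = 1 kPa).
* **Histomorphometry** — from hematoxylin–eosin sections: porosity
  (hollow/total area, %), cell-cluster density (clusters per mm² of solid
  gel) and cluster occupancy (% of solid gel covered), per cluster size
  class: small (<400 µm², <10 cells), medium (400–2000 µm²), large
  (≥2000 µm²); plus nucleus area and shape factor (circularity 4πA/P²).
* **IHC scoring** — from hematoxylin+DAB sections: percent positive cells,
  the intensity-weighted H-score H = 1·p_weak + 2·p_mod + 3·p_strong ∈
  [0, 300], the categorical scale (−/+/++/+++), and the Shimada
  mitosis–karyorrhexis index MKI (% mitotic + karyorrhectic cells; <2% low,
  2–4% intermediate, >4% high).
* **Pore structure** — from SEM-like binary masks: median, interquartile
  range and Fisher skewness of the (right-skewed) pore-area distribution.

Because no public image sets exist for this kind of study, the package ships
a first-class synthetic generator (`gelquant.synthgen`) that renders stained
sections through a Beer–Lambert two-stain optical-density model, draws pore
masks with lognormal areas and samples compression curves
σ = E·ε + c·ε³ + noise — each with a `TruthBundle` recording the exact
per-object ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
import gelquant as gq

# a synthetic Ki67-stained section with known ground truth
params = gq.SectionParams(seed=7, stain_mode="IHC", positive_fraction=0.6)
image, truth = gq.generate_section(params)
row = gq.analyze_section(image, "H-DAB")
print(f"porosity: {row['porosity_pct']:.1f}% (truth {100*truth.true_porosity:.1f}%)")
print(f"clusters: {row['n_clusters']} (truth {len(truth.clusters)}), "
      f"density {row['density_total_per_mm2']:.0f}/mm2, occupancy {row['occupancy_total_pct']:.1f}%")
print(f"Ki67: {row['pct_positive']:.1f}% positive ({row['ihc_category']}), H-score {row['h_score']:.0f}")
print(f"MKI: {row['pct_mk']:.1f}% MK cells -> {row['mki_classification']}")

# a compression curve and its elastic fit
curve, ctruth = gq.generate_stress_strain(gq.CurveParams(E_true_kpa=1.11, seed=0))
fit = gq.fit_youngs_modulus(curve)
print(f"E = {fit.E_kpa:.2f} kPa (truth {ctruth.E_true_kpa} kPa), r2 = {fit.r2:.3f}")
```

prints

```
porosity: 15.0% (truth 15.0%)
clusters: 10 (truth 10), density 180/mm2, occupancy 16.5%
Ki67: 64.8% positive (+++), H-score 130
MKI: 12.6% MK cells -> high
E = 1.10 kPa (truth 1.11 kPa), r2 = 0.970
```

The porosity and cluster count recover the generator's truth; the Ki67
percent-positive and H-score recover the drawn staining (the section-level
realisation of a 60% positive fraction); the measured MKI undercounts the
generated karyorrhexis rate — fragment-halo detection is conservative, see
`docs/methods.md`. The modulus fit recovers the generating slope to ~1% at
the default noise level.

A command-line interface mirrors the library:

```bash
gelquant simulate section --config cfg.json --seed 7 --out out/
gelquant segment --image out/section.png --um-per-px 0.5 --stains HE --out seg/
gelquant mech fit curve.csv --window 0.05:0.15
gelquant report --config run.json --out report/
```

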