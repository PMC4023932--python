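# morphmap

Spatial analysis of digitised museum specimen collections, built around the
kind of data a natural-history collection yields once every pinned specimen
has been databased and manually geocoded: voucher id, sex, female wing-pattern
morph, subspecies, country, verbatim locality and coordinates with a
positional error in km. The motivating system is the African Mocker
Swallowtail *Papilio dardanus*, whose females are polymorphic Batesian
mimics; the package ships the morph/subspecies registry for that species but
every analysis is generic.

It answers three questions a collection-scale biogeographic study asks:

1. **Where was collecting concentrated?** Specimens are filtered to geocodes
   better than 40 km, projected into an Albers equal-area (Africa) plane and
   aggregated to unique localities with specimen counts. Global Moran's I

   *I* = (n/W) Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ²,  zᵢ = xᵢ − x̄,

   z-scored under the randomisation null, is computed over an increasing
   sweep of distance bands; the band with the highest z marks the scale of
   strongest clustering. A circle-count density surface (radius 280 km,
   displayed in 7 quantile classes) is then scored with the Getis-Ord Gi*
   statistic at that band, and localities more than 2.5 standard deviations
   above the mean are labelled sampling hot-spots.
2. **Where does each taxon live?** Per morph group or subspecies, the convex
   hull of its localities is clipped to the environmental classes actually
   occupied: a class raster is block-downsampled to 20 km cells by majority,
   the class under every occurrence is extracted, and hull area in classes
   with zero occurrences is removed.
3. **Are "imperfect" mimics concentrated in the transitional race?** A
   boundary-inclusive point-in-polygon overlay counts imperfect-morph
   specimens inside the union of the transitional subspecies' clipped
   ranges.

A seeded synthetic-data generator plants known structure (collecting
clusters, per-region morph compositions, an environmental class mosaic, a
configurable leakage ε of imperfect morphs outside the transitional region)
so the whole pipeline is testable end to end without any external data.

## Worked example

```sh
morphmap all --outdir demo --seed 7
```

runs simulate → summarise → hotspots → ranges → overlay on the shipped
reference scenario and prints, among other lines:

```
[morphmap] records_generated: 4550
[morphmap] records_geocoded_lt_40km: 2984
[morphmap] localities: 2600
[morphmap] hot_localities: 354
[morphmap] cold_localities: 0
[morphmap] ranges_inferred: 5
[morphmap] imperfect_geocoded: 125
[morphmap] 114 of 125 imperfect specimens inside the meseres+polytrophus range union
```

Reading: of 4550 generated specimens, 2984 survive the 40 km geocoding
filter and collapse to 2600 unique localities; the band sweep places the
strongest clustering at ~241 km (`manifest_hotspots.json`, data-dependent),
354 localities — the three planted collecting clusters — are flagged as
sampling hot-spots and none as cold; five subspecies ranges are inferred
and clipped; and 114/125 ≈ 0.91 of imperfect-mimic specimens fall inside
the transitional-subspecies range union, recovering the scenario's planted
ε = 0.1 leakage. Artifacts (CSV tabulations, `localities.csv` with density,
Gi* z and labels, GeoJSON range polygons, `overlay.json/.csv`, and a JSON
run manifest per stage with config echo and filter counts) land in `demo/`.

The same operations are available as a library:

```python
import morphmap as mm

rs  = mm.read_records("records.csv")
geo = mm.filter_geocoded(rs, 40.0)
pp  = mm.project([r.latitude for r in geo], [r.longitude for r in geo])
analysis = mm.hotspot_pipeline(geo, pp)      # MoranResult list + GiStarResult
```

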