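# strikescape

Feeding-strike kinematics and bite performance landscapes for fishes
filmed with high-speed video and landmarked by pose-estimation software.

Trophic specialists such as scale-eating (lepidophagous) pupfishes remove
material from prey with fast, stereotyped biting strikes. A central
question in ecomorphology is how kinematic traits map onto bite
*performance*: is the mapping a simple ridge, or does it have multiple
optima that could isolate specialists from their generalist ancestors?
`strikescape` provides the full analysis chain for answering this with
gel-biting trials:

1. **Ingestion** of per-strike landmark coordinate exports (HDF5; five
   canonical landmarks: upper jaw tip, lower jaw tip, pupil center,
   opercle margin, jaw joint), pixel-to-mm calibration and short-gap
   interpolation.
2. **Kinematics** — five per-strike variables: peak gape *G* (max
   upper–lower jaw distance), peak jaw protrusion *P* (max pupil–upper
   jaw distance), minimum lower jaw angle at the jaw joint over the
   strike window, time to peak gape (TTPG, from the 20 %-of-peak-gape
   crossing to the peak; one frame at 1100 fps = 0.909 ms), and ram speed
   (eye displacement over the TTPG window / TTPG; mm ms⁻¹ ≡ m s⁻¹).
3. **Bite performance** — length/width/depth of divots removed from
   standardized 15 mm gelatin cubes, typed edge/corner/scrape/miss, with
   volume = L × W × D, validated and joined to kinematics per strike.
4. **Mixed models** — random-intercept (individual) LMMs fitted by
   profiled REML, type II F tests with Satterthwaite denominator degrees
   of freedom, Tukey-adjusted pairwise contrasts of marginal means.
5. **Classification** — linear discriminant analysis of strikes by
   species or strike type on the five kinematic variables, with
   resubstitution and leave-one-out rates against the 4-group 25 % chance
   level.
6. **Performance landscape** — Gaussian additive models with a 2-D
   thin-plate spline *f(G, P)* (basis η(r) = r² log r plus a {1, x, y}
   null space), smoothness selected by exact REML, shrinkage smooths for
   term screening, AIC model selection, surface prediction restricted to
   the data-supported region, and peak/valley detection with topographic
   prominence and saddle heights.
7. **Synthetic studies** — a generator producing landmark trajectories
   and bite outcomes with known ground truth, so every stage above is
   validated by parameter and peak *recovery*, end to end.

## Worked example

Generate a synthetic study (227 strikes, 37 individuals across
generalist, molluscivore, scale-eater and hybrid groups; 130 strikes with
bite dimensions; a bimodal performance function), then run the numbered
analyses:

```bash
python analysis/01_simulate_study.py
python analysis/02_extract_kinematics.py
python analysis/03_mixed_models.py
python analysis/04_lda.py
python analysis/05_performance_landscape.py
```

which prints (abridged):

```
simulated 227 strikes from 37 individuals across 4 groups; 130 strikes carry bite dimensions
extracted 227 strikes (1 failures)
  peak_gape_mm         median |rel err| = 0.0143
peak_gape_mm         species p = 6.864e-07  (sigma2_ind = 0.748, sigma2_res = 0.621)
ttpg_ms              species p = 0.3506  (sigma2_ind = 1.669, sigma2_res = 4.579)
LDA by species     (n=226, 4 groups): 72.1% resubstitution, 68.6% leave-one-out (chance 25.0%)
LDA by strike_type (n=129, 4 groups): 48.8% resubstitution, 40.3% leave-one-out (chance 25.0%)
[length_all] n=129  best model: 2D gape x protrusion smooth  2D smooth edf=18.61
  2 peak(s) at (gape 5.3, protrusion 6.4), (gape 2.6, protrusion 2.0)
```

Reading this: at 0.05 mm landmark noise the extractor recovers peak gape
to ~1.4 % median error; species differ strongly in gape and protrusion
(Satterthwaite type II tests) but not in strike timing; strike types are
only partially separable from kinematics; and the bite-length landscape
over peak gape × protrusion is bimodal, with the AIC-best model the one
containing the 2-D smooth and the two detected optima sitting at the
generator's true peak locations (2.5, 2.0) and (5.0, 6.5). Tables,
surfaces, contour figures and peak JSONs are written under `results/`.

The same steps are available as a CLI for real exported data
(`strikescape ingest | extract | join | model | lda | landscape |
simulate`); see `--help` on each subcommand. If the original strike
table is available, place it at `data/dataset3_kinematics_bites.csv`
(column schema in `tests/test_acceptance.py`) and the dataset-bound
checks run automatically.

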