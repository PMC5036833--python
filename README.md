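# cineshear

Wall shear stress (WSS) and oscillatory shear index (OSI) estimation from 2D
cine phase-contrast MRI (PC-MRI), with a synthetic pulsatile-flow phantom and
a systematic analysis of how spatial and temporal resolution bias the
estimates.

## Who this is for

Quantitative-MRI and vascular-biomechanics researchers who derive
hemodynamic wall parameters from velocity-encoded cine images and need to
know how much of what they measure is physiology and how much is protocol.
The package provides the full chain — acquisition emulation, lumen
segmentation, flow quantification, wall shear estimation, regional
statistics, resolution-sensitivity regression — as a tested, scriptable
library plus a small CLI.

## The model

**Ground truth.** Pulsatile laminar flow in a rigid circular tube. A
carotid-like flow waveform Q(t) (period 1 s, mean 2.7 mL/s, systolic peak
9.1 mL/s) is decomposed into K = 8 Fourier harmonics; each harmonic
Q_k e^{iω_k t} drives the classic Womersley velocity profile

    u_k(r) = Q_k/(πR²) · (1 − J₀(Λ r/R)/J₀(Λ)) / (1 − 2J₁(Λ)/(Λ J₀(Λ))),
    Λ = i^{3/2} α,  α = R√(ω_k/ν),

normalised so each mode carries exactly its prescribed flow; harmonic 0 is
the Poiseuille profile. A skewed (eccentric-apex) profile variant emulates
the asymmetric velocity distribution downstream of a bifurcation.

**Acquisition emulation.** The analytic field is rendered at any pixel
spacing and frame duration with partial-volume box averaging (8× spatial
supersampling), temporal-bin averaging over each frame window, Gaussian
velocity noise σ_v = √2·venc/(π·SNR) per component, and an optional planar
phase-offset error (with a least-squares correction routine).

**Measurement chain.** The lumen is segmented by 2-means clustering of
temporal velocity statistics followed by a closed active contour (snake)
that relaxes onto the wall edge of the temporal-mean speed image. Flow is
the masked pixel sum Q(t) = Σ v_z·ΔA. At each of 64 wall points the
velocity is sampled along the inward normal at offsets d₁ = 1.5 and
d₂ = 3.0 mm, the wall value is pinned to zero, and the spline (the unique
quadratic through the three points) gives the wall shear rate; WSS = μ·WSR
projected wall-tangentially (μ = 1.0·10⁻³ Pa·s, water). OSI per wall point:

    OSI = 0.5·(1 − |Σ_t WSS·Δt| / Σ_t |WSS|·Δt)  ∈ [0, 0.5].

**Sensitivity analysis.** The pipeline runs over 30 protocol resolutions
(0.2–1.0 mm, 9.1–142.9 ms); each response is regressed on resolution by
OLS, with slopes normalised by the response maximum (%/mm, %/100 ms), and
the fixed "best" contour from the finest grid can be re-applied everywhere
to isolate segmentation effects.

## Worked example

```python
import cineshear as cs

geometry = cs.cca_like()                      # R = 2.8 mm circular section
waveform = cs.carotid_waveform()              # mean 2.7 / peak 9.1 mL/s
acq = cs.AcquisitionSpec(pixel_spacing=0.2, frame_duration=24.4,
                         snr=20.0, seed=1)    # finest protocol setting
series = cs.render_series(geometry, waveform, acq)

contour = cs.active_contour_refine(cs.kmeans_initial(series), series)
mask, _ = cs.apply_reference_contour(contour, series)

flow = cs.flow_waveform(series, mask)
field = cs.wss_field(series, contour, viscosity=1e-3, offsets=(1.5, 3.0))
wss_mean, _ = cs.mean_wss(field)
osi = cs.osi(field)
print(f"lumen area : {contour.area:.1f} mm^2")
print(f"mean flow  : {flow.mean_flow:.2f} mL/s")
print(f"peak flow  : {flow.peak_flow:.2f} mL/s")
print(f"mean WSS   : {wss_mean:.3f} Pa")
print(f"mean OSI   : {osi.circumferential_mean:.3f}")
```

prints

```
lumen area : 23.9 mm^2
mean flow  : 2.69 mL/s
peak flow  : 8.88 mL/s
mean WSS   : 0.162 Pa
mean OSI   : 0.006
```

The segmented area matches the true π·2.8² = 24.6 mm² within 3%; the mean
flow recovers the prescribed 2.7 mL/s; the peak is slightly flattened by
the 24.4 ms temporal bin; the WSS sits near the Poiseuille-scale
4μQ/(πR³) ≈ 0.15 Pa; and the OSI is near zero because this waveform never
reverses.

The same analysis runs from the shell:

```bash
cineshear sweep --config config.yaml --out results/ --plots --compare-best
cineshear ingest-summary --table measurements.csv --site CCA --out results/
```

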