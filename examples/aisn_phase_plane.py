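"""The adapting inhibition-stabilized network: bistability and evoked DOWN states.

With adaptation frozen, the E-I phase plane of the aISN shows stable UP
and DOWN states separated by a saddle; the separatrix bounds the UP
basin.  Because the UP state is inhibition-stabilized, a brief *excitatory*
pulse can recruit enough inhibition to push the trajectory across the
separatrix and evoke a transient DOWN state (a slow wave).
"""

from nremdyn import (EIParams, PulseSpec, ei_fixed_points, ei_regime,
                     ei_separatrix, ei_steady_states, evoked_response,
                     separatrix_side)

params = EIParams()   # calibrated Excitable_UP operating point
print(f"full aISN regime: {ei_regime(params)}")
fp = [f for f in ei_steady_states(params) if f[3]][0]
print(f"UP fixed point: r_e = {fp[0]:.3f}, r_i = {fp[1]:.3f}, a = {fp[2]:.3f}")
eig = fp[4]
print(f"leading eigenvalues: {eig[0]:.4f}, {eig[1]:.4f} "
      "(complex pair -> damped E-I oscillation at the DOWN->UP transition)")

portrait = ei_separatrix(params, a_frozen=fp[2])
labels = [(round(f.r_e, 3), f.stability) for f in portrait.fixed_points]
print(f"frozen-a fixed points: {labels}")
print(f"separatrix polyline: {portrait.separatrix.shape[0]} points; "
      f"UP fixed point lies on the "
      f"{separatrix_side(portrait, (fp[0], fp[1]))} side")

trace, evoked = evoked_response(params, PulseSpec(amplitude=2.0, onset=50.0,
                                                  width=10.0, target="r_e"))
print(f"brief excitatory pulse to E evokes a DOWN state: {evoked}")
print("\nAn excitatory kick (e.g. a hippocampal SWR volley) can thus evoke "
      "a neocortical slow wave by transiently breaking the E-I balance.")
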