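# Single-residue annotations used to sanity-check the default element maps.
# aa is the canonical-sequence identity (UniProt P06493 for CDK1, P24941 for
# CDK2); element names refer to ElementMap fields the residue must fall in.
- {kinase: CDK1, residue: 15, aa: Y, element: p_loop}
- {kinase: CDK1, residue: 11, aa: G, element: p_loop}
- {kinase: CDK1, residue: 55, aa: L, element: c_helix}
- {kinase: CDK1, residue: 80, aa: F, element: n_lobe}
- {kinase: CDK1, residue: 81, aa: E, element: hinge}
- {kinase: CDK1, residue: 83, aa: L, element: hinge}
- {kinase: CDK1, residue: 146, aa: D, element: activation_segment}
- {kinase: CDK1, residue: 163, aa: E, element: activation_segment}
- {kinase: CDK2, residue: 15, aa: Y, element: p_loop}
- {kinase: CDK2, residue: 11, aa: G, element: p_loop}
- {kinase: CDK2, residue: 55, aa: L, element: c_helix}
- {kinase: CDK2, residue: 80, aa: F, element: n_lobe}
- {kinase: CDK2, residue: 81, aa: E, element: hinge}
- {kinase: CDK2, residue: 83, aa: L, element: hinge}
- {kinase: CDK2, residue: 145, aa: D, element: activation_segment}
- {kinase: CDK2, residue: 162, aa: E, element: activation_segment}
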