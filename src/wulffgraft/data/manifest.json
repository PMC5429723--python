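{
 "version": 1,
 "files": [
  {
   "file": "lipid_DPPC.json",
   "kind": "lipid",
   "sha256": "e05a3785cb00656e340a4f7415c66012ce90893501c69cc68e8fd3cf4d156990"
  },
  {
   "file": "magnetite_fd3m.cif",
   "kind": "unit-cell",
   "sha256": "1b212babd99b6b0f03e2e4a3a968afa389ea836b557e8a3e5600a310f8a4f36a"
  },
  {
   "file": "monomer_ARA.json",
   "kind": "monomer",
   "sha256": "26ae74a73c9cb5b5aff96d4bdd707e88f496ddda78d5017aabcbe8c9027f24e9"
  },
  {
   "file": "monomer_GAL.json",
   "kind": "monomer",
   "sha256": "a5c552cf61e29f84e6e89464dc5897e9db123d7854421f8d6da6a021d0d2dc44"
  },
  {
   "file": "monomer_GCA.json",
   "kind": "monomer",
   "sha256": "f8ea8c6f3f9473eff062e51f21786d07105b9f1f4d1d87655f736c0e0e19786f"
  },
  {
   "file": "monomer_RHA.json",
   "kind": "monomer",
   "sha256": "f7a8f14655bd11aa8c362ef597ea4a4699566e7209fbd25cde1d1fd8daa1044a"
  }
 ],
 "provenance": "idealized geometry generated by wulffgraft.templates"
}
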