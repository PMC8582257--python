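{
 "fixtures": {
  "8-hydroxyquinoline": {
   "file": "8-hydroxyquinoline.json",
   "sha256": "824c36612c0429915bbfe64812f5d28468a4f2ac14a6063bc3c5a64bfb337a29",
   "source": "Table 4"
  },
  "benzofuran": {
   "file": "benzofuran.json",
   "sha256": "197ed8e2fb3c52d9efa54cd7e7a68b8af67e0445309d45afa4156160f5e48670",
   "source": "Table 5"
  },
  "bh2oh": {
   "file": "bh2oh.json",
   "sha256": "a38d9b66a0cb1c8f45be5837a1ab3a79f8981137d6ff8a21a19f8fc7c4c5ed23",
   "source": "Table 1"
  },
  "bhfoh": {
   "file": "bhfoh.json",
   "sha256": "dc0005d93d3d21b83f0d1a3837f6cd64258ef8ab41cf4025f773041f7c5e13d8",
   "source": "Table 1"
  },
  "bhoh2": {
   "file": "bhoh2.json",
   "sha256": "5b10e6ed1e2644ec76869772f344a40a4a6432ba6a681540f79f6b8cc1f26d62",
   "source": "Table 1"
  },
  "cyanomethylenecyclopropane": {
   "file": "cyanomethylenecyclopropane.json",
   "sha256": "55f8ea0a9b6125dc4265d4bdd1310d156b181550348c770bfdc824d2194c2a1c",
   "source": "Table 3"
  },
  "cyclopropenone": {
   "file": "cyclopropenone.json",
   "sha256": "7b12edad811fcb8c657770b791e45d5d6441537b2515b59a86740a7f712c067c",
   "source": "Table 1"
  },
  "cysteine": {
   "file": "cysteine.json",
   "sha256": "050820743c30a713b08e3ee1cb2ec2c8a55713471a416e8cc3dd6d46359f1e90",
   "source": "Table 6"
  },
  "formaldoxime": {
   "file": "formaldoxime.json",
   "sha256": "8356cbcead87671f7f17d291ac9e16330924ac1105a80411ef448b94dd1443b8",
   "source": "Table 1"
  },
  "guanine": {
   "file": "guanine.json",
   "sha256": "4e64d85085d000eaa3d3894b84bfa2ec74eb8aba2ea87eb3bde76012cf17f10d",
   "source": "Table 7"
  },
  "isoxazole": {
   "file": "isoxazole.json",
   "sha256": "0d7d911877545a3a6888118bf77ea244b90aa1740ba7c4fa898a955d7acd7805",
   "source": "Table 1"
  },
  "oxazole": {
   "file": "oxazole.json",
   "sha256": "fbecd4ed6d7790d8bb7cc904d513b90f977de76bda2fd0cacfa32ab135d6f95d",
   "source": "Table 1"
  },
  "phenol": {
   "file": "phenol.json",
   "sha256": "846ec09ac0ab1b093e3f57893f9dc7367cbe1953c1011bed9603e56091f4ad93",
   "source": "Table 1"
  }
 }
}
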