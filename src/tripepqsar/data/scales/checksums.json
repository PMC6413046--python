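{
 "dpps.tsv": "47cc8c0ed21101ae2df347aadbccfdae6dbca29a980742d9460521c64bd9d517",
 "e_scale.tsv": "90276833e3d6d1757817193e56a2508a0a70846dea04c1d5627eb997fb4468ce",
 "fasgai.tsv": "77dfaffd8805bf64e457a0c11bf79957c656719439df2e9dba777ea4abc93d88",
 "g_scale.tsv": "f64e10877742b3637f4d5d8bc2d05aff8a488904723b5e64d4a084fdff2d6297",
 "hesh.tsv": "fb1aae260e074bf09d148668efa2dcbcdc10fed9e40ea1798271551de92a517e",
 "hsehpcsv.tsv": "d60777d8eac2923ec14aa0644dd465769a2e01cf635db3d34833d3c70b778480",
 "isa_eci.tsv": "411c2c3c059840ae2127707d16aa7380bb4553c9292d8bfdebd4dfdfd9fc8710",
 "ms_whim1.tsv": "e8dd85a4f0f70efda88a9dc6e498347afaca381b4ebf866bbd2a76710b83430d",
 "ms_whim2.tsv": "824d2298e8b6adb03318125003b3ebe86f606508cdb7099f01a5953f1976a102",
 "st_scale.tsv": "a2e9360fcedceb4b00fc365bf629923419dd48a03c74e22fc58bb618e86ea5e5",
 "t_scale.tsv": "2363734c1b1f22b8bae1dcebc0f2b913bd20afa243b28c2036d91c1df95e5b1e",
 "v_scale.tsv": "4a5d1b0c3d4816efda60886862a6359c48b6269383bc5d60b8bbdd896906ded6",
 "vhse.tsv": "aee7c34104f333e3524ebf3e229c5444aa4ed96824b5e8cead57e08adf869e4e",
 "vsw.tsv": "84bf0ab0fc19dffef204000c272babfbce9d69b8b01bca560c7e918f87d3d59c",
 "z5_scale.tsv": "f35e2bc8f1e19e37ab8dcf72cade70b5ad5d44e22c6b82d2dd15508c900667da",
 "z_scale.tsv": "32a979283aaa4afb6aaefa0fd5f7631a9646186ebc4e2e94c6d2f574edd4ecd2"
}
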