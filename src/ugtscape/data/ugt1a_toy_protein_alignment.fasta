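>UGT1A1
MALSSLLACSLRRNIAILVKTQPWTLNSNTERRSNVASIMNVEAEHGSARLMCTRVDSTT
PRPPRTLRDADCCGGRLARRVTVIFCNQARASPWSSDVGLRVITDPHNENERCKVPLVAH
GVLAVRISRVALPQLTFPAPRPAQSVG
>UGT1A3
MALSRDIQSHQDDRRPTLSGSLPLIIVMQTSSQSCYHWRTFPEAEHGSARLMCTRVDSTT
PRPPRTLRDADCCGGRLARRVTVIFCNQARASPWSSDVGLRVITDPHNENERCKVPLVAH
GVLAVRISRVALPQLTFPAPRPAQSVG
>UGT1A4
MADSSIYGRNCAPNSAFLSNTLPWPVDLNHSDRVLAAHMLTLEAEHGSARLMCTRVDSTT
PRPPRTLRDADCCGGRLARRVTVIFCNQARASPWSSDVGLRVITDPHNENERCKVPLVAH
GVLAVRISRVALPQLTFPAPRPAQSVG
>UGT1A5
MALSTMLLSGEVDNITLFRHSVFAVIDYSYWIQNRGAQKLIPEAEHGSARLMCTRVDSTT
PRPPRTLRDADCCGGRLARRVTVIFCNQARASPWSSDVGLRVITDPHNENERCKVPLVAH
GVLAVRISRVALPQLTFPAPRPAQSVG
>UGT1A6
MAYSSFVLLTNKTNNAPGSKFQPFGHRSTTPSFSPRVSKLDPEAEHGSARLMCTRVDSTT
PRPPRTLRDADCCGGRLARRVTVIFCNQARASPWSSDVGLRVITDPHNENERCKVPLVAH
GVLAVRISRVALPQLTFPAPRPAQSVG
>UGT1A7
MTLSSATRTGLLDNIFLDYKSQAYAVRLNGPSHSTPKGIPNIEAEHGSARLMCTRVDSTT
PRPPRTLRDADCCGGRLARRVTVIFCNQARASPWSSDVGLRVITDPHNENERCKVPLVAH
GVLAVRISRVALPQLTFPAPRPAQSVG
>UGT1A8
MPTEVSLMYHLDPRIWIAVTSGKYVIYSNTDQCLSIRSLLSPEAEHGSARLMCTRVDSTT
PRPPRTLRDADCCGGRLARRVTVIFCNQARASPWSSDVGLRVITDPHNENERCKVPLVAH
GVLAVRISRVALPQLTFPAPRPAQSVG
>UGT1A9
MTLSGFVMSLSADYPDAAVKVQPYGVDLQRSLQSPMHGIITWEAEHGSARLMCTRVDSTT
PRPPRTLRDADCCGGRLARRVTVIFCNQARASPWSSDVGLRVITDPHNENERCKVPLVAH
GVLAVRISRVALPQLTFPAPRPAQSVG
>UGT1A10
MSLMSFVSSHLPKNCRSLCKSQVQVDDPNPSNYSFYASILPAEAEHGSARLMCTRVDSTT
PRPPRTLRDADCCGGRLARRVTVIFCNQARASPWSSDVGLRVITDPHNENERCKVPLVAH
GVLAVRISRVALPQLTFPAPRPAQSVG
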