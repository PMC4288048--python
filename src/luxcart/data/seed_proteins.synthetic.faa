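>luxR_seed_A synthetic TraR-like LuxR-family seed (not a natural sequence)
RHTNYAGNFCSWPEDTAKDFYCCPCNDWFYSVWIQTHSIWCENQPNNSFRTFGHQDWIDW
YTWKLVIWCDDYHKDPPIDQKIYNWRMIREFCDIQCWPMWRQDQTTQFMEANDQYSKFCF
KSYFDFREPNHWWCDVQNDLAMALRWFKSFRPPGMDGVPHRKTHFLMFMTMHRLQEAEWY
LLRNKAMGFDYARIRLNLTRHVLYELCGVLDHHVTHKQHFHSTRRMRPESWKPR
>luxR_seed_B synthetic diverged LuxR-family paralog seed
RPRNYAGEFCEQPEDTARRKWCIPCNMAFWVSTIQDHSIWCENQPNNSFLTQGHQKWIDC
YMWCQLGWFDDYHTDPPDNQKRYNWRNVREFPDIQCWPMVRQRQITSFMDDPDQSDKNCF
KIYKDFRVPNFRWCCVQNMLCMAYRVTKSFRCPGNVGHPWCKTHDLLFQAIHRNQNPEWY
MLMCKMMGFPWAAPKMNFTDVSWCILCGVLWHVVWCKNHFHSTREMRWEVAKVR
>luxI_seed_A synthetic TraI-like AHL-synthase-family seed
SNVFAAKLKWIHPTMWDVNLVQWEFMAKSIYIIPRSVVVQAITHTSGIPNIICTKNIVIM
LDPFGGFPTAWPLGFMPFCERMCMWVGQTDWAWFLRNVTFMEIPIWLKTKIQARDKGNGS
IVNKEWNPEILSIKQQILNSHDFPAGYINYRAKFLNCDSGVSFPESTAYIFLLNDNICKH
VSMWEQHTKMTHRRCTKDQL
>luxI_seed_B synthetic diverged AHL-synthase-family seed
SNKSLYKRGWGMPDCWDANLHQWEFMAKSIAIIPRYVSVQSIKPWSGIPNIILFKIIVIM
IDHWGGFCEPKPAGFMPFCYLRCMNKGQTDSRFFLRNVEMMLGPLVLGTMISAYSKGGGS
ICNKFWNTNQDSEKKMNLAPHDFPAGYINERAKFLNEDSGVSFKVGTAYIFLFNNNKAKE
VSIWEMHEKWSHRRCTYDQL
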